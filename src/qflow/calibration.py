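"""Bead standard curve and absolute calibration to receptors per cell.

Quantitative flow cytometry converts arbitrary fluorescence units into
absolute plasma-membrane receptor numbers using calibration beads that
carry known numbers of fluorophores. A least-squares line through
(log10 fluorophores-per-bead, log10 median intensity) defines the
instrument response; inverting it maps each cell's intensity to
fluorophores, and a stoichiometry factor (receptors per fluorophore,
default 1:1 for PE-conjugated antibodies) converts fluorophores to
receptors.

Events with non-positive intensity cannot be placed on the log-log curve;
they are assigned zero receptors and counted, so population compositions
are conserved while log-domain analyses can report the exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .io import EventTable

__all__ = [
    "BeadCalibrationSet",
    "CalibrationCurve",
    "CalibrationError",
    "CalibratedValues",
    "fit_bead_curve",
    "calibrate",
    "read_beads_csv",
    "write_beads_csv",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class BeadCalibrationSet:
    """Known fluorophores-per-bead for each peak plus observed intensities."""

    known_fluorophores: tuple[float, ...]
    intensities: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        known = np.asarray(self.known_fluorophores, dtype=float)
        if known.size < 2:
            raise CalibrationError("need at least 2 bead peaks to fit a line")
        if np.any(np.diff(known) <= 0):
            raise CalibrationError("known fluorophores-per-bead must be strictly increasing")
        if np.any(known <= 0):
            raise CalibrationError("known fluorophores-per-bead must be positive")
        if len(self.intensities) != known.size:
            raise CalibrationError("one intensity set required per peak")
        for i, obs in enumerate(self.intensities):
            if np.asarray(obs).size < 1:
                raise CalibrationError(f"peak {i} has no observed intensities")

    @classmethod
    def from_arrays(cls, known, intensities) -> "BeadCalibrationSet":
        return cls(
            tuple(float(v) for v in known),
            tuple(np.asarray(obs, dtype=float) for obs in intensities),
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """log10(intensity) = intercept + slope * log10(fluorophores/bead)."""

    slope: float
    intercept: float
    r_squared: float
    receptors_per_fluorophore: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"calibration slope must be positive, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise CalibrationError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.receptors_per_fluorophore <= 0:
            raise CalibrationError("receptors_per_fluorophore must be positive")

    def intensity_for(self, receptors: np.ndarray) -> np.ndarray:
        """Forward map receptors/cell -> expected intensity (a.u.)."""
        receptors = np.asarray(receptors, dtype=float)
        fluor = receptors / self.receptors_per_fluorophore
        out = np.zeros_like(fluor)
        pos = fluor > 0
        out[pos] = 10.0 ** (self.intercept + self.slope * np.log10(fluor[pos]))
        return out


@dataclass(frozen=True)
class CalibratedValues:
    """Per-event receptors/cell plus the non-positive-intensity exclusion tally."""

    receptors: np.ndarray
    n_excluded_nonpositive: int


def fit_bead_curve(
    beads: BeadCalibrationSet, receptors_per_fluorophore: float = 1.0
) -> CalibrationCurve:
    """Least-squares log-log line through per-peak median intensities."""
    medians = np.array([float(np.median(obs)) for obs in beads.intensities])
    if np.any(medians <= 0):
        bad = int(np.argmax(medians <= 0))
        raise CalibrationError(
            f"peak {bad} (known={beads.known_fluorophores[bad]:g}) has "
            f"non-positive median intensity {medians[bad]:g}; cannot take log"
        )
    x = np.log10(np.asarray(beads.known_fluorophores, dtype=float))
    y = np.log10(medians)
    fit = _st.linregress(x, y)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        receptors_per_fluorophore=receptors_per_fluorophore,
    )


def calibrate(events: EventTable, channel: str, curve: CalibrationCurve) -> CalibratedValues:
    """Convert one channel's intensities to absolute receptors/cell.

    receptors = receptors_per_fluorophore * 10**((log10 I - intercept)/slope)
    for I > 0; events with I <= 0 get zero receptors and are tallied.
    """
    intensity = events.channel_values(channel)
    receptors = np.zeros(intensity.shape, dtype=float)
    pos = intensity > 0
    receptors[pos] = curve.receptors_per_fluorophore * 10.0 ** (
        (np.log10(intensity[pos]) - curve.intercept) / curve.slope
    )
    return CalibratedValues(receptors=receptors, n_excluded_nonpositive=int(np.sum(~pos)))


def read_beads_csv(path) -> BeadCalibrationSet:
    """Read a long-form bead table: columns known_fluorophores, intensity."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("known_fluorophores", "intensity"):
        if col not in df.columns:
            raise CalibrationError(f"{path}: bead CSV needs a {col!r} column")
    grouped = df.groupby("known_fluorophores", sort=True)["intensity"]
    known = list(grouped.groups)
    return BeadCalibrationSet.from_arrays(
        known, [grouped.get_group(k).to_numpy(dtype=float) for k in known]
    )


def write_beads_csv(beads: BeadCalibrationSet, path) -> None:
    import pandas as pd

    frames = [
        pd.DataFrame({"known_fluorophores": k, "intensity": np.asarray(obs, dtype=float)})
        for k, obs in zip(beads.known_fluorophores, beads.intensities)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
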