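"""Event-table data model and CSV input/output.

The central container is :class:`EventTable`: one row per acquired event
(cell), one column per instrument channel, intensities in arbitrary
fluorescence units. Negative intensities are legal — baseline-subtracting
instruments emit them — and are preserved at I/O time; log-domain stages
handle them explicitly downstream.

CSV is the canonical, bit-exact interchange format (header row = channel
names, UTF-8, "." decimal). FCS support lives in :mod:`qflow.fcs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "EventTableError",
    "read_events_csv",
    "write_events_csv",
]


class EventTableError(ValueError):
    """Raised when event data violates the table invariants."""


@dataclass
class EventTable:
    """Per-event channel intensities plus panel metadata.

    Parameters
    ----------
    sample_id : str
        Identifier for the acquisition tube/sample.
    channels : list of str
        Ordered channel names (markers or scatter); must be unique.
    intensities : ndarray of shape (n_events, n_channels)
        Raw fluorescence in arbitrary units. Finite values only;
        negatives are permitted.
    panel : dict, optional
        Map from channel name to the stained marker (e.g.
        ``{"PE-A": "VEGFR1"}``). Channels absent from the panel are
        treated as unstained/utility channels (scatter, viability).
    """

    sample_id: str
    channels: list[str]
    intensities: np.ndarray
    panel: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise EventTableError("intensities must be a 2-D matrix")
        n, p = self.intensities.shape
        if n < 1:
            raise EventTableError("an event table needs at least one event")
        if len(self.channels) != p:
            raise EventTableError(
                f"{len(self.channels)} channel names for {p} intensity columns"
            )
        if len(set(self.channels)) != len(self.channels):
            raise EventTableError("channel names must be unique")
        if not np.all(np.isfinite(self.intensities)):
            raise EventTableError("intensities must be finite")
        unknown = set(self.panel) - set(self.channels)
        if unknown:
            raise EventTableError(f"panel refers to unknown channels: {sorted(unknown)}")

    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]

    def channel_values(self, channel: str) -> np.ndarray:
        """Return the intensity column for one channel."""
        try:
            idx = self.channels.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not present; available: {self.channels}"
            ) from None
        return self.intensities[:, idx]

    def marker_channel(self, marker: str) -> str:
        """Resolve a stained marker name to its channel via the panel."""
        for ch, m in self.panel.items():
            if m == marker:
                return ch
        raise KeyError(f"marker {marker!r} not in panel {self.panel}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, columns=self.channels)


def read_events_csv(path, panel: dict[str, str] | None = None, sample_id: str | None = None) -> EventTable:
    """Read an event table from CSV (header row = channel names).

    Non-numeric body cells raise :class:`EventTableError` naming the
    offending row and column; column order is preserved.
    """
    try:
        # round_trip parser: values re-read exactly as written; NA-like
        # strings are not silently converted to missing values
        df = pd.read_csv(
            path,
            header=0,
            skip_blank_lines=True,
            float_precision="round_trip",
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        raise EventTableError(f"{path}: empty file, no header row") from None
    if df.shape[0] == 0:
        raise EventTableError(f"{path}: header only, no events")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        if pd.api.types.is_numeric_dtype(df[col]):
            values[:, j] = df[col].to_numpy(dtype=float)
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            # +2: 1-based data rows plus the header line
            raise EventTableError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} at "
                f"line {bad[0] + 2}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    sid = sample_id if sample_id is not None else str(path)
    return EventTable(sid, [str(c) for c in df.columns], values, panel or {})


def write_events_csv(table: EventTable, path) -> None:
    """Write an event table to CSV at full float precision (round-trip safe)."""
    table.to_dataframe().to_csv(path, index=False, float_format="%.17g")
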