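"""Hierarchical threshold gating and population composition.

The gating scheme mirrors standard dissociated-tumor practice: dead cells
are excluded on a viability stain (live = negative), hematopoietic cells
on CD45, then CD34 and CD133 positivity pick out endothelial-like cells
and stem-like cells from the CD45-negative pool. Gates are 1-D intensity
thresholds arranged in a tree; "positive" means intensity >= threshold.

Events descend from the root, taking the first child whose predicate they
satisfy; events that satisfy no child at some internal node are reported
as "ungated". Each event therefore receives exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GateSpec
from .io import EventTable

__all__ = [
    "UNGATED",
    "CompositionReport",
    "GateNode",
    "GatingError",
    "apply_gates",
    "composition",
    "suggest_threshold",
]

UNGATED = "ungated"


class GatingError(ValueError):
    pass


@dataclass
class GateNode:
    """One node of the gate tree (see module docstring for semantics)."""

    marker: str | None = None
    threshold: float | None = None
    direction: str | None = None  # "negative" | "positive"
    label: str | None = None
    children: list["GateNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.marker is not None:
            if self.threshold is None or self.direction is None:
                raise GatingError(f"gate on {self.marker!r} needs threshold and direction")
            if not np.isfinite(self.threshold):
                raise GatingError(f"gate threshold on {self.marker!r} must be finite")
            if self.direction not in ("negative", "positive"):
                raise GatingError(f"unknown gate direction {self.direction!r}")
        if not self.children and self.label is None:
            raise GatingError("leaf gate nodes must carry a population label")

    @classmethod
    def from_spec(cls, spec: GateSpec) -> "GateNode":
        return cls(
            marker=spec.marker,
            threshold=spec.threshold,
            direction=spec.direction,
            label=spec.label,
            children=[cls.from_spec(c) for c in spec.children],
        )

    def leaf_labels(self) -> list[str]:
        if not self.children:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaf_labels())
        return out

    def markers(self) -> set[str]:
        out = set() if self.marker is None else {self.marker}
        for child in self.children:
            out |= child.markers()
        return out


@dataclass(frozen=True)
class CompositionReport:
    """Event counts and percentages of live cells per population."""

    counts: dict[str, int]
    percents: dict[str, float]
    total_live: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population": list(self.counts),
                "count": list(self.counts.values()),
                "percent_of_live": [self.percents[p] for p in self.counts],
            }
        )


def _matches(node: GateNode, events: EventTable, mask: np.ndarray) -> np.ndarray:
    if node.marker is None:
        return mask
    values = events.channel_values(node.marker)
    if node.direction == "positive":
        return mask & (values >= node.threshold)
    return mask & (values < node.threshold)


def apply_gates(events: EventTable, tree: GateNode) -> np.ndarray:
    """Assign each event its leaf population label (or "ungated").

    Deterministic: children are tested in declaration order and the first
    match wins. Raises :class:`KeyError` naming any gate marker that has
    no channel in the event table.
    """
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        raise GatingError(f"leaf labels must be unique, got {labels}")
    for marker in sorted(tree.markers()):
        if marker not in events.channels:
            raise KeyError(
                f"gate marker {marker!r} has no channel in the event table "
                f"(channels: {events.channels})"
            )

    out = np.full(events.n_events, UNGATED, dtype=object)

    def descend(node: GateNode, mask: np.ndarray) -> None:
        if not node.children:
            out[mask] = node.label
            return
        remaining = mask.copy()
        for child in node.children:
            selected = _matches(child, events, remaining)
            if selected.any():
                descend(child, selected)
            remaining &= ~selected
        # events matching no child stay "ungated"

    root_mask = _matches(tree, events, np.ones(events.n_events, dtype=bool))
    descend(tree, root_mask)
    return np.array([str(v) for v in out], dtype=object)


def composition(labels: np.ndarray, live_labels: list[str] | None = None) -> CompositionReport:
    """Population composition as percentages of live events.

    ``live_labels`` defaults to every label except "ungated" (dead and
    out-of-scheme events fail a gate and end up ungated).
    """
    labels = np.asarray(labels, dtype=object)
    if live_labels is None:
        live_labels = [l for l in dict.fromkeys(labels.tolist()) if l != UNGATED]
    live_mask = np.isin(labels, live_labels)
    total = int(live_mask.sum())
    if total == 0:
        raise GatingError("no live events; composition is undefined")
    counts = {lab: int(np.sum(labels == lab)) for lab in live_labels}
    percents = {lab: 100.0 * c / total for lab, c in counts.items()}
    return CompositionReport(counts=counts, percents=percents, total_live=total)


def suggest_threshold(values: np.ndarray, grid: int = 512) -> float:
    """Suggest a threshold at the density valley of a bimodal channel.

    Runs a Gaussian kernel density estimate over log10 of the positive
    intensities and returns the deepest minimum between the two outermost
    modes, mapped back to intensity units. Helper only — production
    thresholds come from the configuration.
    """
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    pos = values[values > 0]
    if pos.size < 10:
        raise GatingError("need at least 10 positive events to suggest a threshold")
    x = np.log10(pos)
    kde = gaussian_kde(x)
    grid_x = np.linspace(x.min(), x.max(), grid)
    dens = kde(grid_x)
    interior = slice(1, -1)
    is_min = (dens[interior] < dens[:-2]) & (dens[interior] < dens[2:])
    minima = np.flatnonzero(is_min) + 1
    if minima.size == 0:
        raise GatingError("channel does not look bimodal; no density valley found")
    valley = minima[np.argmin(dens[minima])]
    return float(10.0 ** grid_x[valley])
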