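"""End-to-end orchestration: read -> calibrate -> gate -> stats -> mixture
-> quadratic entropy -> target scoring.

`run_pipeline` executes the full analysis described by one
:class:`~qflow.config.PipelineConfig` and returns a
:class:`PipelineResult` whose reports are emitted as CSV/JSON when an
output directory is given. Every random stage (bootstrap intervals, EM
restarts) derives its seed deterministically from the config seed, so a
config runs to byte-identical outputs.

Populations below the configured minimum cell count (default 50) are
reported in the composition table only; their per-marker statistics are
skipped with a warning. Per-marker fit failures are logged and skipped —
the pipeline halts only on I/O or configuration errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationCurve, calibrate, fit_bead_curve, read_beads_csv
from .config import PipelineConfig
from .fcs import read_fcs
from .gating import CompositionReport, GateNode, apply_gates, composition
from .io import EventTable, read_events_csv
from .mixture import MixtureFit, select_bic, summarize_components
from .scoring import TargetScore, rank_targets, score_target
from .stats import (
    DegenerateDistributionError,
    EnsembleStats,
    QEResult,
    ReceptorDistribution,
    ensemble_concentration,
    receptor_qe,
)

__all__ = ["MarkerResult", "PipelineResult", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(base_seed: int, *names: str) -> int:
    """Deterministic sub-seed for a named pipeline stage, below 2**31."""
    tag = zlib.crc32("|".join(names).encode("utf-8"))
    return (base_seed * 1_000_003 + tag) % (2**31)


@dataclass(frozen=True)
class MarkerResult:
    population: str
    marker: str
    stats: EnsembleStats
    qe: QEResult
    fit: MixtureFit
    score: TargetScore
    n_cells: int
    n_excluded_nonpositive: int


@dataclass
class PipelineResult:
    composition: CompositionReport
    curve: CalibrationCurve
    results: list[MarkerResult]
    skipped: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def stats_table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "population": r.population,
                    "marker": r.marker,
                    "n_cells": r.n_cells,
                    "n_excluded_nonpositive": r.n_excluded_nonpositive,
                    "geometric_mean": r.stats.geometric_mean,
                    "arithmetic_mean": r.stats.arithmetic_mean,
                    "gm_ci95_low": r.stats.ci95_low,
                    "gm_ci95_high": r.stats.ci95_high,
                    "qe": r.qe.qe,
                    "qe_class": r.qe.heterogeneity_class,
                    "k_components": r.fit.k,
                    "component_class": r.fit.heterogeneity_class(),
                    "bic": r.fit.bic,
                }
            )
        return pd.DataFrame(rows)

    def fits_json(self) -> str:
        payload = {}
        for r in self.results:
            payload[f"{r.population}/{r.marker}"] = {
                "k": r.fit.k,
                "components": [
                    {
                        "weight": c.weight,
                        "mu_log10": c.mu_log10,
                        "sigma_log10": c.sigma_log10,
                        "receptors_per_cell": c.receptors_per_cell,
                    }
                    for c in r.fit.components
                ],
                "log_likelihood": r.fit.log_likelihood,
                "bic": r.fit.bic,
                "bic_table": {str(k): v for k, v in sorted(r.fit.bic_table.items())},
                "n": r.fit.n,
            }
        return json.dumps(
            {"fits": payload, "provenance": self.provenance},
            indent=2,
            sort_keys=True,
        )

    def targets_table(self) -> pd.DataFrame:
        return rank_targets([r.score for r in self.results])

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.composition.to_dataframe().to_csv(out / "composition.csv", index=False)
        self.stats_table().to_csv(out / "stats.csv", index=False)
        (out / "fits.json").write_text(self.fits_json())
        if self.results:
            self.targets_table().to_csv(out / "targets.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True)
        )


def _read_events(config: PipelineConfig) -> EventTable:
    if not config.events_path:
        raise FileNotFoundError("config has no events_path")
    path = Path(config.events_path)
    if not path.exists():
        raise FileNotFoundError(f"events file not found: {path}")
    if path.suffix.lower() == ".fcs":
        table = read_fcs(path, sample_id=config.sample_id)
        if config.panel:
            table.panel = dict(config.panel)
        return table
    return read_events_csv(path, panel=dict(config.panel), sample_id=config.sample_id)


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full analysis for one configuration."""
    events = _read_events(config)
    logger.info("loaded %d events, %d channels", events.n_events, len(events.channels))

    if not config.calibration.beads_path:
        raise FileNotFoundError("config has no calibration.beads_path")
    beads_path = Path(config.calibration.beads_path)
    if not beads_path.exists():
        raise FileNotFoundError(f"bead calibration file not found: {beads_path}")
    beads = read_beads_csv(beads_path)
    curve = fit_bead_curve(beads, config.calibration.receptors_per_fluorophore)
    logger.info(
        "bead curve: slope=%.4f intercept=%.4f r2=%.5f",
        curve.slope, curve.intercept, curve.r_squared,
    )

    tree = GateNode.from_spec(config.gates)
    labels = apply_gates(events, tree)
    leaf_labels = tree.leaf_labels()
    comp = composition(labels, live_labels=leaf_labels)

    background: dict[str, float] = {}
    if config.calibration.background_path:
        ctrl = read_events_csv(config.calibration.background_path, panel=dict(config.panel))
        for channel in config.panel:
            cal = calibrate(ctrl, channel, curve)
            background[channel] = float(np.median(cal.receptors))

    results: list[MarkerResult] = []
    skipped: list[dict] = []
    params = config.analysis
    for pop in leaf_labels:
        mask = labels == pop
        n_pop = int(mask.sum())
        if n_pop < params.min_cells:
            if n_pop:
                logger.warning(
                    "population %r has %d cells (<%d); composition-only",
                    pop, n_pop, params.min_cells,
                )
            skipped.append({"population": pop, "n_cells": n_pop, "reason": "below min_cells"})
            continue
        for channel, marker in config.panel.items():
            try:
                cal = calibrate(events, channel, curve)
                receptors = cal.receptors[mask]
                if channel in background:
                    receptors = np.maximum(receptors - background[channel], 0.0)
                dist = ReceptorDistribution(
                    population=pop,
                    marker=marker,
                    values=receptors,
                    n_excluded_nonpositive=int(np.sum(receptors <= 0)),
                )
                seed = stage_seed(config.seed, pop, marker)
                stats = ensemble_concentration(
                    dist, n_bootstrap=params.bootstrap_samples, seed=seed
                )
                qe = receptor_qe(dist, n_bins=params.bins)
                fit = select_bic(
                    dist.values,
                    k_range=range(params.k_min, params.k_max + 1),
                    seed=seed,
                    n_restarts=params.n_restarts,
                )
                score = score_target(
                    dist,
                    qe,
                    fit,
                    ensemble_gm=stats.geometric_mean,
                    reference_gm=config.reference.get(marker),
                    criteria=config.criteria,
                )
            except (DegenerateDistributionError, ValueError) as exc:
                logger.warning("skipping %s/%s: %s", pop, marker, exc)
                skipped.append({"population": pop, "marker": marker, "reason": str(exc)})
                continue
            results.append(
                MarkerResult(
                    population=pop,
                    marker=marker,
                    stats=stats,
                    qe=qe,
                    fit=fit,
                    score=score,
                    n_cells=n_pop,
                    n_excluded_nonpositive=dist.n_excluded_nonpositive,
                )
            )

    provenance = {
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "qflow_version": __version__,
        "n_events": events.n_events,
        "calibration": {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
            "receptors_per_fluorophore": curve.receptors_per_fluorophore,
        },
    }
    result = PipelineResult(
        composition=comp,
        curve=curve,
        results=results,
        skipped=skipped,
        provenance=provenance,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
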