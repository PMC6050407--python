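# Methods

This note records the models, conventions and numerical choices behind
`qflow`, and what the synthetic benchmark does and does not establish.

## Signal model and calibration

Cell fluorescence is assumed linear-scale (no instrument log
amplification) in arbitrary units, with negative values permitted —
baseline-subtracting cytometers emit them, and they are preserved through
I/O. Calibration beads with known fluorophores-per-bead F define the
instrument response by least squares on (log₁₀ F, log₁₀ median intensity);
the median per peak is robust to the occasional aggregate or dim outlier.
Inverting the line and multiplying by a receptors-per-fluorophore factor
(default 1.0, i.e. 1:1 fluorophore:antibody:receptor as is typical for PE
conjugates; configurable because stoichiometry is assay-specific) yields
receptors/cell. Events with non-positive intensity cannot be placed on the
log-log curve; they are assigned zero receptors rather than dropped, so
population counts are conserved, and every log-domain stage reports its
exclusion tally. An optional background subtraction (median calibrated
signal of an unstained/isotype control) exists but is off by default so it
cannot silently shift results.

## Gating

Gates are 1-D intensity thresholds in a tree (live → CD45⁻ → CD34⁺/CD133⁺
leaves); 2-D polygon gates are out of scope. The boundary convention is
fixed for exactness: *positive* means intensity ≥ threshold. "Live" is
negative on the viability channel, mirroring dye-exclusion staining.
Thresholds are configuration inputs, as in manual gating practice; a
helper suggests the kernel-density valley of a bimodal channel but is
never applied implicitly.

## Ensemble statistics

The ensemble summary is the geometric mean over positive receptor values
(receptor distributions are log-normal-like, so the geometric mean is the
natural location), with the arithmetic mean reported alongside and a
seeded percentile bootstrap (default 500–1,000 resamples) for the 95%
interval of the geometric mean.

## Quadratic entropy

QE is Rao's quadratic entropy over B equally spaced bins on the
log₁₀-receptor axis, QE = Σᵢ Σⱼ pᵢ pⱼ |cᵢ − cⱼ| with bin-center distances,
over *ordered* pairs (no ½ factor; halve externally for the
unordered-pair convention). Conventions and choices:

* **Log domain.** QE is computed on log₁₀ receptors/cell; the 0.2–0.7
  band quoted for homogeneous cultured cells is only dimensionally
  plausible in log units, and a decade is the natural unit of receptor
  variation.
* **Bin centers, not member means.** Using per-bin member means would
  make QE depend on within-bin data; midpoints make it a pure function of
  the binned distribution.
* **B = 500 bins** by default, spanning [min, max] of the sample's log₁₀
  positive values, top edge right-closed. An optional fixed-range mode
  supports cross-sample comparability; per-sample ranges are the default
  because they follow the data with no tuning.
* **Degenerate inputs.** Fewer than two distinct positive values means
  zero spread: QE = 0 by definition, class "low". Zero-receptor cells are
  excluded from binning and tallied.
* **Complexity.** Production QE uses the sorted prefix-sum identity
  (O(B)); tests enforce agreement with the O(B²) double sum to 1e-12.
* **Classification.** QE < 0.7 is "low", QE ≥ 0.7 "high"; the boundary
  itself counts as high.

## Log-normal mixture decomposition

Each population × marker distribution is fitted with k = 1…9 Gaussian
components on log₁₀ values by expectation-maximization; the lowest BIC
wins, with ties broken toward smaller k (the anti-overfitting intent of
using BIC in the first place). Conventions, stated because BIC constants
differ between software packages: free parameters = 3k − 1; LL is the
natural-log likelihood in log₁₀ space; BIC = (3k−1)·ln n − 2·LL.

Numerical choices: k = 1 uses the closed-form MLE. For k ≥ 2, EM runs to
a relative log-likelihood change below 1e-8 or 500 iterations, best of 5
restarts — one quantile partition of the sorted sample plus four random
starts — all driven by one seed, so fits are bit-reproducible. A log-SD
floor of 1e-3 prevents degenerate spike collapse. The E-step works on
(k, n) arrays with the component axis leading so reductions run over
contiguous memory; for the sample sizes this package targets the working
set is cache-resident, which is what makes BIC selection over nine
candidate counts with restarts practical on one core. Likelihood
monotonicity is asserted on every run. Component counts with fewer than
10·k positive values are skipped and logged. scikit-learn's
`GaussianMixture` is used in the test suite as an independent cross-check
of fitted parameters and of the BIC convention, never as the
implementation.

## Target scoring

Defaults encode the targeting guidelines: availability ≥ 70% of cells
above 6,000 receptors/cell; QE < 0.7; specificity ≥ 2-fold over a
healthy-tissue reference (reported ~5-fold VEGFR2 and ~4-fold PDGFRα
elevations comfortably clear it; no published cutoff exists, so 2.0 is a
deliberately permissive default and configurable). A missing reference
marks the score "unscored" on specificity instead of failing it, since
healthy baselines are usually unavailable. The combination-candidate rule
operationalizes "high concentration on a small subpopulation" as a fitted
component with weight ≤ 0.10 and mean ≥ 10× the ensemble geometric mean
(the motivating example, ~41,000 VEGFR1/cell over a ~3,600 ensemble, is
≈ 11×); both thresholds are configurable.

## Synthetic benchmark

The generator draws true receptors/cell from per-population log-normal
mixtures, maps them through the truth calibration curve, and multiplies by
log-normal measurement noise with stated CV (default 0.2 — flow intensity
noise is approximately log-normal; the log-noise has zero mean so
geometric means are recovered without bias). Gating channels are bimodal
with negative/positive regimes 2.5 decades apart, which makes
midpoint-threshold gating exact by construction.

The bundled scenario encodes a glioblastoma-PDX-like panel: live-cell
fractions 62.46% bulk tumor, 5.20% human EC-like, exactly 6× that
(31.2%) mouse EC-like, 0.9% stem-like, and a 0.24% residual CD45⁺
hematopoietic fraction that closes the live-cell budget (the four headline
fractions alone sum to 99.76%). Human EC-like markers carry the minority
subpopulations of interest: 8% of cells at 12× the ~21,000/cell ensemble
EGFR mean (IGFR mirrors it), 10% at 41,000 VEGFR1/cell over a ~3,600
ensemble, 8% at 65,700 Tie2/cell over a ~5,000 ensemble, and a 35%
VEGFR2 component at 18,500/cell with the majority mode placed so that
≥ 70% of cells exceed 6,000 receptors/cell. Published VEGFR2 anchors are
mutually inconsistent under a log-normal mixture (a ~5,800/cell ensemble
geometric mean cannot coexist with 70% availability above 6,000 and a 35%
component at 18,500), so the scenario prioritizes the targeting anchors;
its VEGFR2 ensemble comes out near 10,700/cell. Where only an ensemble
mean is known a marker is a single component with σ(log₁₀) = 0.3; mouse
EC-like markers use σ = 0.45 (the more heterogeneous pool) and the bulk
population's EGFR/IGFR are widely split bimodals (QE ≈ 1). All σ values
are generator choices — no published per-population SDs exist.

What the benchmark does *not* emulate: doublets, debris, spectral
spillover, acquisition drift, or 2-D gate geometry. Passing tests
therefore demonstrate correctness of calibration, gating logic, the
heterogeneity indices and the scoring rules under a realistic noise model
— not robustness to instrument artifacts.

## Problem sizes and determinism

Tests run the benchmark at 20,000 events (within the realistic
10,000–35,000 live-cell acquisition range) and the mixture-selection study
at n = 10,000 with 50 seeds; `scripts/acceptance.py` uses 20 seeds for its
selection study and 20,000-event pipeline runs, sizes chosen so a full
reproduction completes in minutes on one core. Every random stage
(generation, bootstrap, EM restarts) derives its seed deterministically
from the configured seed, so pipeline outputs are byte-identical across
runs; populations below 50 cells are reported composition-only (the
smallest analyzed population in the benchmark, ~0.9% of ~19,000 live
events ≈ 170 cells, clears it, and the 0.24% hematopoietic residual
usually does not).

## Known limitations

* FCS support covers list-mode FCS 3.0/3.1 (float or integer data, both
  byte orders); FCS 2.0 and analysis segments are rejected or ignored.
  CSV is the canonical, bit-exact interchange format.
* Gates are 1-D thresholds; quadrant-style reasoning on 2-D plots must be
  expressed as nested 1-D gates.
* The mixture model assumes log-normal components; skewed or
  heavy-tailed subpopulations will be approximated by extra components,
  inflating k.
* QE depends on the binning range; comparing QE across samples with very
  different supports is best done in fixed-range mode.
* Specificity scoring needs an external healthy-tissue reference; none is
  bundled.
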