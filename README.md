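# qflow

Quantitative flow cytometry (qFlow) analysis: convert single-cell
fluorescence into **absolute plasma-membrane receptor concentrations**
(receptors/cell), resolve cell populations by hierarchical gating, quantify
receptor heterogeneity, and score receptors as drug targets.

The package is written for researchers characterizing receptor tyrosine
kinase (RTK) heterogeneity in dissociated tumor specimens — for example
glioblastoma patient-derived xenografts, where human tumor cells, mouse and
human endothelial-like cells (EC-like, CD45⁻CD34⁺) and stem-like cells
(CD45⁻CD133⁺) coexist and carry very different receptor loads.

## Method

1. **Bead calibration.** Beads carrying known numbers of fluorophores define
   a log-log standard curve, log₁₀ I = b + a·log₁₀ F. Inverting it and
   applying a receptors-per-fluorophore stoichiometry factor maps each
   cell's intensity I to absolute receptors/cell.
2. **Hierarchical gating.** 1-D threshold gates (live → CD45⁻ → CD34⁺ /
   CD133⁺) assign each event one population label; composition is reported
   as percentages of live cells.
3. **Ensemble statistics.** Per population × marker: geometric and
   arithmetic mean receptors/cell with a bootstrap 95% interval.
4. **Cell-by-cell heterogeneity.** Two complementary indices:
   * **Mixture components** — the distribution of log₁₀ receptors/cell is
     decomposed into k = 1…9 log-normal components by
     expectation-maximization; the Bayesian Information Criterion
     (BIC = (3k−1)·ln n − 2·LL) selects k. k ≤ 2 is read as low
     heterogeneity, k > 2 as high.
   * **Quadratic entropy (QE)** — Rao's index over B = 500 equally spaced
     log₁₀ bins, QE = Σᵢⱼ pᵢpⱼ|cᵢ−cⱼ|: the expected log-distance (in
     decades) between two randomly drawn cells. QE < 0.7 is low
     heterogeneity; homogeneous cultured cells typically land in 0.2–0.7.
5. **Target scoring.** A receptor is a *primary target* on a population when
   it is highly available (≥ 70% of cells above 6,000 receptors/cell),
   homogeneous (QE < 0.7), and tumor-specific (≥ 2-fold over a healthy
   reference, skipped when no reference exists). A receptor carried at
   ≥ 10× the ensemble mean by a minority component (≤ 10% of cells) is
   flagged as a *combination-therapy candidate* — a potential alternative
   signaling route invisible to bulk averages.

Because raw tumor specimens are not portable, the package ships a
synthetic-data generator with known ground truth (`qflow.synthetic`),
including a benchmark scenario that encodes a realistic glioblastoma-PDX
panel (62.46% bulk tumor cells, 5.20% human EC-like, 6× more mouse EC-like,
0.9% stem-like cells; minority subpopulations such as 10% of human EC-like
cells at ~41,000 VEGFR1/cell).

## Worked example

```sh
qflow simulate --scenario paperlike --n 20000 --seed 11 --out-dir demo
qflow run --config demo/config.json --out-dir demo/results
```

or in Python:

```python
from qflow import load_config, run_pipeline
result = run_pipeline(load_config("demo/config.json"))
print(result.composition.percents)
print(result.stats_table().query("population == 'human EC-like'"))
```

prints (abridged):

```
{'GSC': 0.86, 'human EC-like': 5.06, 'mouse EC-like': 31.14,
 'other': 62.65, 'hematopoietic': 0.29}

marker  geometric_mean       qe qe_class  k_components
VEGFR1     3614.921603 0.460840      low             2
VEGFR2    10682.627012 0.350867      low             1
  Tie2     4778.943608 0.485311      low             2
  EGFR    21597.897329 0.427672      low             2
```

Reading: the live-cell composition matches the generating truth within
sampling error; human EC-like cells carry ~3,600 VEGFR1/cell on average but
split into two log-normal components — the fitted minority component
(~9% of cells at ~47,000 VEGFR1/cell, ~13× the ensemble mean) flags VEGFR1
as a combination-therapy candidate, while VEGFR2 (78% of cells above 6,000
receptors/cell, QE 0.35) scores as a primary target.

Reports are written as `composition.csv`, `stats.csv`, `fits.json`,
`targets.csv` and `provenance.json`; the run is byte-identical under a
fixed seed.

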