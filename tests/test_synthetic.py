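import math

import numpy as np
import pytest

from qflow.synthetic import (
    MarkerComponent,
    PopulationSpec,
    SyntheticGroundTruth,
    generate_beads,
    generate_cells,
    paperlike_scenario,
)


def single_pop_truth(mu=3.0, sigma=0.2, noise_cv=0.0, **kw):
    pop = PopulationSpec(
        name="p", fraction=1.0, marker_models={"M": (MarkerComponent(1.0, mu, sigma),)}
    )
    kw.setdefault("calibration_slope", 1.0)
    kw.setdefault("calibration_intercept", 0.0)
    kw.setdefault("dead_fraction", 0.0)
    return SyntheticGroundTruth(populations=(pop,), noise_cv=noise_cv, **kw)


class TestGenerateCells:
    def test_component_parameters_recovered_at_large_n(self):
        """Law of large numbers: log10 of true receptors matches (mu, sigma)."""
        _, truth_df = generate_cells(single_pop_truth(), n=10_000, seed=3)
        logs = np.log10(truth_df["true_M"].to_numpy())
        assert abs(logs.mean() - 3.0) < 0.01
        assert abs(logs.std() - 0.2) < 0.01

    def test_population_fractions_binomial(self):
        a = PopulationSpec("a", 0.9, {"M": (MarkerComponent(1.0, 3, 0.2),)})
        b = PopulationSpec("b", 0.1, {"M": (MarkerComponent(1.0, 4, 0.2),)})
        truth = SyntheticGroundTruth(populations=(a, b), dead_fraction=0.0)
        _, truth_df = generate_cells(truth, n=10_000, seed=4)
        counts = truth_df["population"].value_counts()
        assert abs(counts["a"] - 9_000) <= 100  # +-1% of n
        assert abs(counts["b"] - 1_000) <= 100

    def test_same_seed_identical(self):
        truth = paperlike_scenario(seed=0)
        e1, t1 = generate_cells(truth, 500, seed=9)
        e2, t2 = generate_cells(truth, 500, seed=9)
        np.testing.assert_array_equal(e1.intensities, e2.intensities)
        assert t1.equals(t2)

    def test_noise_free_identity_calibration_gives_true_intensity(self):
        events, truth_df = generate_cells(single_pop_truth(), n=100, seed=5)
        np.testing.assert_allclose(
            events.channel_values("PE_M"), truth_df["true_M"], rtol=1e-12
        )

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            generate_cells(single_pop_truth(), n=0, seed=1)
        with pytest.raises(ValueError, match="sum"):
            SyntheticGroundTruth(
                populations=(
                    PopulationSpec("a", 0.5, {"M": (MarkerComponent(1.0, 3, 0.2),)}),
                )
            )


class TestGenerateBeads:
    def test_zero_noise_medians_on_curve(self):
        truth = single_pop_truth()
        beads = generate_beads(truth, peaks=[1e3, 1e4, 1e5], n_per_peak=50, seed=0)
        for known, obs in zip(beads.known_fluorophores, beads.intensities):
            assert np.median(obs) == pytest.approx(known, rel=1e-12)  # identity curve

    def test_geometric_cv_matches_requested(self):
        truth = single_pop_truth(noise_cv=0.1)
        beads = generate_beads(truth, peaks=[1e3, 1e4], n_per_peak=500, seed=0)
        for obs in beads.intensities:
            gcv = math.exp(np.std(np.log(obs))) - 1.0
            assert 0.08 <= gcv <= 0.12

    def test_degenerate_peaks_rejected(self):
        truth = single_pop_truth()
        with pytest.raises(ValueError):
            generate_beads(truth, peaks=[1e3], n_per_peak=10)
        with pytest.raises(ValueError, match="increasing"):
            generate_beads(truth, peaks=[1e4, 1e3], n_per_peak=10)


class TestPaperlikeScenario:
    def test_encoded_composition(self):
        truth = paperlike_scenario()
        frac = {p.name: p.fraction for p in truth.populations}
        assert frac["other"] == pytest.approx(0.6246)
        assert frac["human EC-like"] == pytest.approx(0.0520)
        assert frac["GSC"] == pytest.approx(0.0090)
        assert frac["mouse EC-like"] / frac["human EC-like"] == pytest.approx(6.0)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)

    def test_minority_subpopulations_encoded(self):
        truth = paperlike_scenario()
        hec = {p.name: p for p in truth.populations}["human EC-like"]

        egfr = hec.marker_models["EGFR"]
        minority = min(egfr, key=lambda c: c.weight)
        ensemble_mu = sum(c.weight * c.mu_log10 for c in egfr)
        assert minority.weight == pytest.approx(0.08)
        assert 10 ** (minority.mu_log10 - ensemble_mu) == pytest.approx(12.0, rel=1e-6)
        assert 10**ensemble_mu == pytest.approx(21_000, rel=1e-6)

        vegfr1 = min(hec.marker_models["VEGFR1"], key=lambda c: c.weight)
        assert vegfr1.weight == pytest.approx(0.10)
        assert 10**vegfr1.mu_log10 == pytest.approx(41_000, rel=1e-6)

        tie2 = min(hec.marker_models["Tie2"], key=lambda c: c.weight)
        assert tie2.weight == pytest.approx(0.08)
        assert 10**tie2.mu_log10 == pytest.approx(65_700, rel=1e-6)

    def test_nine_marker_panel_and_reference(self):
        truth = paperlike_scenario()
        assert len(truth.markers) == 9
        assert set(truth.healthy_reference) == {"VEGFR2", "PDGFRa"}

    def test_serializes_to_json(self):
        payload = paperlike_scenario().to_json()
        assert "human EC-like" in payload and "notes" in payload
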