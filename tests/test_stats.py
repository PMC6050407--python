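import itertools

import numpy as np
import pytest

from qflow.stats import (
    BinnedDistribution,
    DegenerateDistributionError,
    ReceptorDistribution,
    bin_distribution,
    ensemble_concentration,
    quadratic_entropy,
    receptor_qe,
)


def qe_brute_force(probabilities, centers):
    """O(B^2) double sum over all ordered bin pairs — the reference oracle."""
    total = 0.0
    for i, pi in enumerate(probabilities):
        for j, pj in enumerate(probabilities):
            total += pi * pj * abs(centers[i] - centers[j])
    return total


def dist(values, population="p", marker="m"):
    return ReceptorDistribution(population, marker, np.asarray(values, dtype=float))


class TestEnsembleConcentration:
    def test_constant_sample(self):
        s = ensemble_concentration(dist([3_100.0] * 10), seed=0)
        assert s.geometric_mean == pytest.approx(3_100.0)
        assert s.arithmetic_mean == pytest.approx(3_100.0)

    def test_closed_form_two_values(self):
        s = ensemble_concentration(dist([100.0, 10_000.0]), seed=0)
        assert s.geometric_mean == pytest.approx(1_000.0, rel=1e-12)
        assert s.arithmetic_mean == pytest.approx(5_050.0, rel=1e-12)

    def test_zeros_excluded_from_geometric_mean_but_tallied(self):
        s = ensemble_concentration(dist([0.0, 100.0, 10_000.0]), seed=0)
        assert s.geometric_mean == pytest.approx(1_000.0)
        assert s.n_zero == 1 and s.n_positive == 2

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            ensemble_concentration(dist([0.0, 0.0]), seed=0)

    def test_bootstrap_interval_brackets_mean_and_is_seeded(self, rng):
        values = 10 ** rng.normal(3.5, 0.3, 2_000)
        a = ensemble_concentration(dist(values), seed=7)
        b = ensemble_concentration(dist(values), seed=7)
        assert (a.ci95_low, a.ci95_high) == (b.ci95_low, b.ci95_high)
        assert a.ci95_low < a.geometric_mean < a.ci95_high


class TestBinDistribution:
    def test_two_bin_edges_and_centers(self):
        b = bin_distribution(dist([10.0, 100.0, 1_000.0]), n_bins=2)
        np.testing.assert_allclose(b.edges, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(b.centers, [1.5, 2.5])

    def test_maximum_lands_in_last_bin_once(self):
        b = bin_distribution(dist([10.0, 1_000.0]), n_bins=4)
        assert b.probabilities[-1] == pytest.approx(0.5)
        assert b.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(10):
            values = 10 ** rng.normal(3, 0.6, rng.integers(10, 400))
            b = bin_distribution(dist(values), n_bins=int(rng.integers(2, 500)))
            assert abs(b.probabilities.sum() - 1.0) <= 1e-12

    def test_identical_values_single_support_error(self):
        with pytest.raises(DegenerateDistributionError, match="single support"):
            bin_distribution(dist([5.0, 5.0, 5.0]), n_bins=10)

    def test_no_positive_values_error(self):
        with pytest.raises(DegenerateDistributionError):
            bin_distribution(dist([0.0, 0.0]), n_bins=10)


def binned(probabilities, lo, hi):
    p = np.asarray(probabilities, dtype=float)
    return BinnedDistribution(np.linspace(lo, hi, p.size + 1), p / p.sum())


class TestQuadraticEntropy:
    def test_single_bin_mass_is_zero(self):
        r = quadratic_entropy(binned([1.0, 0.0, 0.0], 0.0, 3.0))
        assert r.qe == 0.0
        assert r.heterogeneity_class == "low"

    def test_two_equal_masses_one_decade_apart(self):
        r = quadratic_entropy(binned([0.5, 0.5], 2.5, 4.5))  # centers 3 and 4
        assert r.qe == pytest.approx(0.5, abs=1e-15)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            B = int(rng.integers(2, 500))
            p = rng.dirichlet(np.ones(B))
            b = binned(p, 0.0, float(rng.uniform(0.5, 5.0)))
            assert quadratic_entropy(b).qe == pytest.approx(
                qe_brute_force(b.probabilities, b.centers), abs=1e-12
            )

    def test_invariant_under_appended_empty_bins(self):
        base = binned([0.25, 0.75], 1.0, 3.0)
        padded = binned([0.25, 0.75, 0.0, 0.0], 1.0, 5.0)  # same width, empty top bins
        assert quadratic_entropy(padded).qe == pytest.approx(
            quadratic_entropy(base).qe, abs=1e-14
        )

    def test_invariant_under_bin_permutation(self, rng):
        """QE depends only on (p, c) pairs, not their order (oracle-level)."""
        p = rng.dirichlet(np.ones(30))
        c = np.linspace(0, 3, 30)
        perm = rng.permutation(30)
        assert qe_brute_force(p, c) == pytest.approx(qe_brute_force(p[perm], c[perm]), abs=1e-13)

    def test_scales_linearly_with_center_spacing(self, rng):
        p = rng.dirichlet(np.ones(40))
        base = quadratic_entropy(binned(p, 0.0, 2.0)).qe
        scaled = quadratic_entropy(binned(p, 0.0, 6.0)).qe  # centers scaled by 3
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_maximized_by_half_mass_at_extremes(self):
        """Brute force over a coarse simplex at B=3: 0.5/0/0.5 is the max."""
        grid = np.arange(0.0, 1.0001, 0.05)
        best, best_p = -1.0, None
        c = np.array([0.0, 0.5, 1.0])
        for p1, p2 in itertools.product(grid, grid):
            p3 = 1.0 - p1 - p2
            if p3 < -1e-12:
                continue
            q = qe_brute_force([p1, p2, max(p3, 0.0)], c)
            if q > best:
                best, best_p = q, (p1, p2, max(p3, 0.0))
        assert best_p == pytest.approx((0.5, 0.0, 0.5), abs=1e-9)
        assert best == pytest.approx(0.5)

    def test_two_point_qe_increases_with_separation(self):
        qes = [quadratic_entropy(binned([0.5, 0.5], 0.0, d)).qe for d in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(qes) > 0)

    def test_classification_threshold(self):
        from qflow.stats import QEResult

        assert quadratic_entropy(binned([0.5, 0.5], 2.5, 4.5)).heterogeneity_class == "low"
        # the low/high boundary itself counts as high
        assert QEResult(0.7, 500).heterogeneity_class == "high"
        assert QEResult(np.nextafter(0.7, 0.0), 500).heterogeneity_class == "low"


class TestReceptorQE:
    def test_degenerate_distribution_qe_zero(self):
        assert receptor_qe(dist([5.0] * 20)).qe == 0.0

    def test_healthy_like_sample_in_low_band(self, rng):
        """A single log-normal with sigma <= 0.3 lands in the 0.2-0.7 band
        typical of homogeneous cultured cells."""
        values = 10 ** rng.normal(3.7, 0.3, 10_000)
        qe = receptor_qe(dist(values), n_bins=500).qe
        assert 0.2 < qe < 0.7

    def test_wide_mixture_classified_high(self, rng):
        values = np.concatenate(
            [10 ** rng.normal(3.0, 0.4, 5_000), 10 ** rng.normal(4.6, 0.4, 5_000)]
        )
        r = receptor_qe(dist(values), n_bins=500)
        assert r.qe > 0.7 and r.heterogeneity_class == "high"
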