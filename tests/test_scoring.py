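import numpy as np
import pytest

from qflow.mixture import MixtureComponent, MixtureFit
from qflow.scoring import TargetCriteria, rank_targets, score_target
from qflow.stats import QEResult, ReceptorDistribution


def make_fit(components, n=1000):
    comps = tuple(MixtureComponent(*c) for c in components)
    k = len(comps)
    return MixtureFit(
        k=k, components=comps, log_likelihood=0.0,
        bic=(3 * k - 1) * np.log(n), n=n, seed=0, n_iter=1, converged=True,
    )


def make_dist(values, marker="VEGFR2"):
    return ReceptorDistribution("human EC-like", marker, np.asarray(values, dtype=float))


class TestScoreTarget:
    def test_available_homogeneous_specific_is_primary(self):
        """73% of cells above 6,000 receptors/cell, QE 0.20, 5-fold over
        healthy reference: all three criteria met."""
        values = np.concatenate([np.full(73, 10_000.0), np.full(27, 1_000.0)])
        score = score_target(
            make_dist(values),
            QEResult(0.20, 500),
            make_fit([(1.0, 4.0, 0.2)]),
            ensemble_gm=10_000.0,
            reference_gm=2_000.0,
        )
        assert score.availability == pytest.approx(0.73)
        assert score.specificity_fold == pytest.approx(5.0)
        assert score.primary_target

    def test_all_cells_below_floor_never_primary(self):
        values = np.full(100, 500.0)
        score = score_target(
            make_dist(values), QEResult(0.0, 500), make_fit([(1.0, 2.7, 0.2)]),
            ensemble_gm=500.0,
        )
        assert score.availability == 0.0
        assert not score.primary_target

    def test_high_qe_blocks_primary(self):
        values = np.full(100, 10_000.0)
        score = score_target(
            make_dist(values), QEResult(1.0, 500), make_fit([(1.0, 4.0, 0.2)]),
            ensemble_gm=10_000.0,
        )
        assert not score.primary_target

    def test_missing_reference_skips_specificity(self):
        values = np.full(100, 10_000.0)
        score = score_target(
            make_dist(values), QEResult(0.2, 500), make_fit([(1.0, 4.0, 0.2)]),
            ensemble_gm=10_000.0,
        )
        assert score.primary_target and not score.specificity_scored
        assert score.specificity_fold is None

    def test_insufficient_fold_blocks_primary(self):
        values = np.full(100, 10_000.0)
        score = score_target(
            make_dist(values), QEResult(0.2, 500), make_fit([(1.0, 4.0, 0.2)]),
            ensemble_gm=10_000.0, reference_gm=9_000.0,
        )
        assert not score.primary_target

    def test_minority_high_component_flags_combination(self):
        """10% subpopulation at 41,000 receptors over a ~3,600 ensemble."""
        fit = make_fit([(0.90, 3.44, 0.25), (0.10, np.log10(41_000.0), 0.25)])
        score = score_target(
            make_dist(np.full(100, 3_600.0), marker="VEGFR1"),
            QEResult(0.5, 500), fit, ensemble_gm=3_600.0,
        )
        assert score.combination_candidate
        assert score.minority_weight == pytest.approx(0.10)
        assert score.minority_receptors == pytest.approx(41_000.0, rel=1e-6)

    def test_majority_high_component_not_combination(self):
        fit = make_fit([(0.35, 4.27, 0.25), (0.65, 3.0, 0.25)])
        score = score_target(
            make_dist(np.full(100, 2_000.0)), QEResult(0.5, 500), fit, ensemble_gm=2_000.0
        )
        assert not score.combination_candidate

    def test_availability_monotone_in_receptor_counts(self, rng):
        values = 10 ** rng.normal(3.7, 0.3, 500)
        base = score_target(
            make_dist(values), QEResult(0.3, 500), make_fit([(1.0, 3.7, 0.3)]),
            ensemble_gm=5_000.0,
        )
        boosted = score_target(
            make_dist(values * 2.0), QEResult(0.3, 500), make_fit([(1.0, 4.0, 0.3)]),
            ensemble_gm=10_000.0,
        )
        assert boosted.availability >= base.availability

    def test_determinism(self, rng):
        values = 10 ** rng.normal(3.8, 0.3, 200)
        args = (make_dist(values), QEResult(0.4, 500), make_fit([(1.0, 3.8, 0.3)]))
        a = score_target(*args, ensemble_gm=6_000.0, reference_gm=1_000.0)
        b = score_target(*args, ensemble_gm=6_000.0, reference_gm=1_000.0)
        assert a == b

    def test_configurable_criteria(self):
        values = np.full(100, 10_000.0)
        strict = TargetCriteria(availability_receptors_min=20_000.0)
        score = score_target(
            make_dist(values), QEResult(0.2, 500), make_fit([(1.0, 4.0, 0.2)]),
            ensemble_gm=10_000.0, criteria=strict,
        )
        assert score.availability == 0.0


class TestRankTargets:
    def scores(self):
        def s(marker, avail, primary, combo):
            values = np.full(10, 10_000.0 if avail else 100.0)
            fit = make_fit(
                [(0.08, 5.0, 0.2), (0.92, 3.0, 0.2)] if combo else [(1.0, 3.5, 0.2)]
            )
            return score_target(
                make_dist(values, marker=marker),
                QEResult(0.2 if primary else 0.9, 500),
                fit,
                ensemble_gm=float(np.mean(values)),
            )

        return s

    def test_primary_sorted_by_availability_then_candidates(self):
        make = self.scores()
        hi = make("A", True, True, False)
        combo = make("C", False, False, True)
        dud = make("D", False, False, False)
        table = rank_targets([dud, combo, hi])
        assert list(table["marker"]) == ["A", "C", "D"]

    def test_permutation_stable(self):
        make = self.scores()
        items = [make(m, False, False, False) for m in "ABCD"]
        a = rank_targets(items)
        b = rank_targets(items[::-1])
        assert set(a["marker"]) == set(b["marker"])
        assert list(a["tier"]) == list(b["tier"])
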