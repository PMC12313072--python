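"""Profile correlation, identification, aggregation, statistics, power."""

import numpy as np
import pytest
from scipy import stats

from neurosound import evaluation as ev
from neurosound.features import AcousticSummary, MelSpectrogram


class TestProfileCorrelation:
    def test_identity_and_sign_flip(self, rng):
        Y = rng.normal(size=(20, 6))
        r, mean_r, _ = ev.profile_correlation(Y, Y)
        np.testing.assert_allclose(r, 1.0)
        r2, m2, _ = ev.profile_correlation(Y, -Y)
        np.testing.assert_allclose(r2, -1.0)

    def test_constant_units_excluded_and_counted(self, rng):
        Y = rng.normal(size=(10, 4))
        D = Y.copy()
        Y[:, 2] = 3.0
        r, mean_r, n_const = ev.profile_correlation(Y, D)
        assert n_const == 1 and np.isnan(r[2])

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.profile_correlation(rng.normal(size=(2, 3)),
                                   rng.normal(size=(2, 3)))

    def test_spearman_agrees_on_monotone_data(self, rng):
        Y = rng.normal(size=(30, 5))
        D = np.exp(Y)  # monotone transform: spearman 1, pearson < 1
        _, m_s, _ = ev.profile_correlation(Y, D, metric="spearman")
        np.testing.assert_allclose(m_s, 1.0)


class TestPairwiseIdentification:
    def test_pool_of_50_gives_49_pairs(self, rng):
        pool = [rng.normal(size=12) for _ in range(50)]
        o = ev.pairwise_identification(pool[7] + 0.01, pool, 7)
        assert o.n_pairs == 49

    def test_true_probe_scores_one(self, rng):
        pool = [rng.normal(size=12) for _ in range(10)]
        assert ev.pairwise_identification(pool[3], pool, 3).accuracy == 1.0

    def test_random_probe_matches_monte_carlo_null(self, rng):
        """Independent probes score at chance, agreeing with a brute-force
        simulation of the null."""
        pool = [rng.normal(size=30) for _ in range(20)]
        accs = [ev.pairwise_identification(rng.normal(size=30), pool,
                                           i % 20).accuracy
                for i in range(300)]
        mean = np.mean(accs)
        # oracle: direct simulation of comparing iid correlations
        n = 300 * 19
        band = 3 * 0.5 / np.sqrt(n)
        assert abs(mean - 0.5) < band + 0.03

    def test_exact_ties_score_half(self):
        pool = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        probe = np.array([1.0, 1.0])  # equally dissimilar to both
        o = ev.pairwise_identification(probe, pool, 0, metric="euclidean")
        assert o.n_correct == 0.5

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        probe = rng.normal(size=8)
        o1 = ev.pairwise_identification(probe, [a, b], 0)
        o2 = ev.pairwise_identification(probe, [a, b], 1)
        assert o1.n_correct + o2.n_correct == 1.0

    def test_undefined_probe_excluded(self):
        pool = [np.array([1.0]), np.array([2.0])]
        assert ev.pairwise_identification(None, pool, 0) is None
        assert ev.pairwise_identification(np.array([np.nan]), pool, 0) is None

    def test_within_category_scope_limits_lures(self, rng):
        pool = [rng.normal(size=5) for _ in range(6)]
        cats = ["a", "a", "a", "b", "b", "b"]
        o = ev.pairwise_identification(pool[0], pool, 0,
                                       scope="within_category",
                                       categories=cats)
        assert o.n_pairs == 2
        assert o.candidate_scope == "within_category"

    def test_scalar_euclidean_metric(self):
        pool = [np.array([100.0]), np.array([300.0]), np.array([150.0])]
        o = ev.pairwise_identification(np.array([110.0]), pool, 0,
                                       metric="euclidean")
        assert o.accuracy == 1.0


class TestBlockAggregate:
    def _outcome(self, sid, w, acc):
        return ev.IdentificationOutcome(sample_id=f"{sid}/{w}", n_pairs=10,
                                        n_correct=acc * 10)

    def test_fifty_stimuli_give_fifty_blocks(self):
        outs = [self._outcome(f"s{i}", w, 0.8)
                for i in range(50) for w in range(3)]
        blocks = ev.block_aggregate(outs)
        assert len(blocks) == 50
        assert all(b.accuracy == pytest.approx(0.8) for b in blocks)

    def test_block_mean_equals_window_mean_in_balanced_design(self, rng):
        accs = rng.random((20, 3))
        outs = [self._outcome(f"s{i}", w, accs[i, w])
                for i in range(20) for w in range(3)]
        blocks = ev.block_aggregate(outs)
        np.testing.assert_allclose(np.mean([b.accuracy for b in blocks]),
                                   accs.mean())

    def test_missing_window_rejected(self):
        outs = [self._outcome("s0", 0, 1.0), self._outcome("s0", 1, 1.0)]
        with pytest.raises(ValueError):
            ev.block_aggregate(outs)


class TestCI95:
    def test_constant_points_zero_width(self):
        s = ev.ci95([0.7] * 10)
        assert s.ci95_low == pytest.approx(0.7) == s.ci95_high

    def test_bernoulli_closed_form(self):
        pts = [0.0, 1.0] * 25
        s = ev.ci95(pts)
        se = np.std(pts, ddof=1) / np.sqrt(50)
        half = stats.t.ppf(0.975, 49) * se
        assert s.mean == 0.5
        assert s.ci95_low == pytest.approx(0.5 - half)
        assert s.ci95_high == pytest.approx(0.5 + half)

    def test_brackets_mean(self, rng):
        pts = rng.random(30)
        s = ev.ci95(pts)
        assert s.ci95_low <= s.mean <= s.ci95_high

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            ev.ci95([0.5])


class TestAttention:
    def test_majority_vote_and_counts(self):
        scores = {f"t{i}": [1.0, 1.0, 0.0] for i in range(48)}
        outcomes, stat = ev.attention_evaluate(scores)
        assert len(outcomes) == 48
        assert all(o.correct for o in outcomes)

    def test_tie_windows_majority_rule(self):
        outcomes, _ = ev.attention_evaluate({"a": [0.5, 0.5, 1.0],
                                             "b": [0.5, 0.5, 0.0]})
        by_id = {o.trial_id: o.correct for o in outcomes}
        assert by_id["a"] is True      # sum 2.0 > 1.5
        assert by_id["b"] is False     # sum 1.0 <= 1.5

    def test_binomial_tail_matches_direct_summation(self):
        scores = {f"t{i}": [1.0, 1.0, 1.0] if i < 33 else [0.0, 0.0, 0.0]
                  for i in range(48)}
        _, stat = ev.attention_evaluate(scores)
        direct = sum(stats.binom.pmf(k, 48, 0.5) for k in range(33, 49))
        assert stat.p_value == pytest.approx(direct, rel=1e-12)

    def test_wrong_window_count_rejected(self):
        with pytest.raises(ValueError):
            ev.attention_evaluate({"a": [1.0, 0.0]})

    def test_window_score_levels(self):
        a = np.array([1.0, 0.0, 0.0])
        u = np.array([0.0, 1.0, 0.0])
        r = np.array([0.9, 0.1, 0.0])
        assert ev.attention_window_score(r, a, u) == 1.0
        assert ev.attention_window_score(r, u, a) == 0.0
        assert ev.attention_window_score(a, a, a) == 0.5


class TestPower:
    def test_required_n_ttest_medium_effect(self):
        assert ev.required_n_ttest(0.5, alpha=0.05, power=0.80) == 27

    def test_required_n_binomial_07(self):
        assert ev.required_n_binomial(0.7, 0.5, alpha=0.05, power=0.80) == 37

    def test_huge_effect_needs_minimum_n(self):
        assert ev.required_n_ttest(50.0) == 2

    def test_certain_success_closed_form(self):
        # with p1 = 1 the test succeeds iff k = n is significant:
        # (1/2)^n <= alpha first at n = 5 for alpha = 0.05
        assert ev.required_n_binomial(1.0, 0.5, alpha=0.05, power=0.80) == 5

    def test_monte_carlo_power_at_returned_n(self, rng):
        n = ev.required_n_ttest(0.5)
        draws = rng.normal(0.5, 1.0, size=(20_000, n))
        tstat = draws.mean(1) / (draws.std(1, ddof=1) / np.sqrt(n))
        power = np.mean(tstat > stats.t.ppf(0.95, n - 1))
        assert power >= 0.80 - 0.01

        nb = ev.required_n_binomial(0.7)
        k_crit = ev.binomial_critical_k(nb, 0.5, 0.05)
        sims = rng.binomial(nb, 0.7, size=20_000)
        assert np.mean(sims >= k_crit) >= 0.80 - 0.01

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            ev.required_n_ttest(-1.0)
        with pytest.raises(ValueError):
            ev.required_n_binomial(0.4, 0.5)


class TestPerturbedIdentification:
    def test_texture_degrades_pixel_match_of_perfect_recon(self, small_specs):
        pool = small_specs[:6]
        o_plain = ev.pairwise_identification(
            pool[0].values.ravel(), [s.values.ravel() for s in pool], 0)
        o_tex = ev.perturbed_identification(pool[0], pool, 0, "texture",
                                            seed=3)
        assert o_plain.accuracy == 1.0
        assert o_tex.n_correct <= o_plain.n_correct

    def test_shuffle_requires_window(self, small_specs):
        with pytest.raises(ValueError):
            ev.perturbed_identification(small_specs[0], small_specs[:3], 0,
                                        "shuffle")

    def test_unknown_perturbation_rejected(self, small_specs):
        with pytest.raises(ValueError):
            ev.perturbed_identification(small_specs[0], small_specs[:3], 0,
                                        "reverse")


class TestHierarchicalIdentification:
    def test_true_wave_scores_one_at_every_stage(self, small_specs,
                                                 default_net):
        pool = small_specs[:5]
        for stage in range(1, 7):
            o = ev.hierarchical_identification(pool[1], pool, default_net,
                                               stage, 1)
            assert o.accuracy == 1.0

    def test_invalid_stage_rejected(self, small_specs, default_net):
        with pytest.raises(ValueError):
            ev.hierarchical_identification(small_specs[0], small_specs[:3],
                                           default_net, 7, 0)
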