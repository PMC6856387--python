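"""Comparison statistics: t tests from summaries, correlation, bootstrap,
Hellinger transform, PCA contract, consensus selection."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from dfpmaa.stats import (
    GroupSummary,
    SelectionRecord,
    consensus_select,
    hellinger,
    one_sample_t_from_summary,
    paired_bootstrap_increase,
    pca_decompose,
    pearson_p_from_r,
    pearson_r,
    welch_t_from_summary,
)


class TestWelchFromSummary:
    def test_identical_groups(self):
        g = GroupSummary(10.0, 1.0, 5)
        t, df, p = welch_t_from_summary(g, g)
        assert t == 0 and p == pytest.approx(1.0)

    def test_agrees_with_raw_welch_to_1e9(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(5, 2, 8), rng.normal(3, 1, 12)
        t, df, p = welch_t_from_summary(GroupSummary.from_raw(a), GroupSummary.from_raw(b))
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_pooled_agrees_with_student(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(5, 2, 8), rng.normal(3, 2, 12)
        t, df, p = welch_t_from_summary(
            GroupSummary.from_raw(a), GroupSummary.from_raw(b), pooled=True
        )
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert df == 18

    def test_agrees_with_permutation_oracle(self):
        # moderate two-group difference: the t p-value matches an exhaustive
        # label-permutation p-value within Monte-Carlo-free enumeration error
        rng = np.random.default_rng(42)
        a, b = rng.normal(2.0, 1.0, 6), rng.normal(0.0, 1.0, 6)
        _, _, p = welch_t_from_summary(GroupSummary.from_raw(a), GroupSummary.from_raw(b))
        pooled = np.concatenate([a, b])
        obs = abs(sps.ttest_ind(a, b, equal_var=False).statistic)
        exceed = total = 0
        for idx in itertools.combinations(range(12), 6):
            mask = np.zeros(12, bool)
            mask[list(idx)] = True
            t_perm = sps.ttest_ind(pooled[mask], pooled[~mask], equal_var=False).statistic
            total += 1
            exceed += abs(t_perm) >= obs - 1e-12
        assert p == pytest.approx(exceed / total, abs=0.01)

    def test_degenerate_zero_sems(self):
        assert welch_t_from_summary(GroupSummary(1, 0, 3), GroupSummary(1, 0, 3))[2] == 1.0
        assert welch_t_from_summary(GroupSummary(2, 0, 3), GroupSummary(1, 0, 3))[2] == 0.0


class TestOneSampleFromSummary:
    def test_mean_equals_mu0(self):
        t, df, p = one_sample_t_from_summary(GroupSummary(5.0, 1.0, 10), 5.0)
        assert t == 0 and p == pytest.approx(1.0)

    def test_agrees_with_raw_one_sample(self):
        rng = np.random.default_rng(2)
        x = rng.normal(4, 2, 15)
        t, df, p = one_sample_t_from_summary(GroupSummary.from_raw(x), 3.0)
        ref = sps.ttest_1samp(x, 3.0)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_sign_symmetry(self):
        g = GroupSummary(10.0, 2.0, 6)
        _, _, p_hi = one_sample_t_from_summary(g, 14.0)
        _, _, p_lo = one_sample_t_from_summary(g, 6.0)
        assert p_hi == pytest.approx(p_lo)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_p_from_r_matches_t_formula(self):
        r, n = 0.7, 12
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert pearson_p_from_r(r, n) == pytest.approx(2 * sps.t.sf(t, n - 2))

    def test_p_matches_data_route(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = x + rng.normal(scale=0.8, size=20)
        r, p = pearson_r(x, y)
        assert p == pytest.approx(pearson_p_from_r(r, 20), rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPairedBootstrap:
    def test_all_positive_differences_small_p(self):
        rng = np.random.default_rng(4)
        before = rng.normal(10, 1, 30)
        after = before + rng.uniform(2, 3, 30)
        assert paired_bootstrap_increase(before, after, B=10_000, seed=5) <= 0.005

    def test_no_change_gives_p_one(self):
        x = np.arange(10.0)
        assert paired_bootstrap_increase(x, x, B=1000, seed=6) == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        b, a = rng.normal(size=12), rng.normal(size=12) + 0.5
        assert paired_bootstrap_increase(b, a, 2000, seed=8) == paired_bootstrap_increase(
            b, a, 2000, seed=8
        )

    def test_converges_to_exhaustive_enumeration_at_n3(self):
        # diffs (1, 2, -4): 19 of the 27 equally likely resamples have mean <= 0
        before = np.array([0.0, 0.0, 0.0])
        after = np.array([1.0, 2.0, -4.0])
        exact = 19 / 27
        B = 50_000
        p = paired_bootstrap_increase(before, after, B=B, seed=9)
        expected = (1 + B * exact) / (B + 1)
        assert p == pytest.approx(expected, abs=4 * np.sqrt(exact * (1 - exact) / B))


class TestHellinger:
    def test_uniform(self):
        assert hellinger([1, 1, 1, 1]) == pytest.approx([0.5] * 4)

    def test_simple_fractions(self):
        assert hellinger([9, 16]) == pytest.approx([0.6, 0.8])

    def test_unit_norm(self):
        rng = np.random.default_rng(10)
        v = hellinger(rng.uniform(0, 10, 40))
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hellinger([0, 0])


class TestPcaDecompose:
    def test_collinear_points_explained_by_first_component(self):
        t = np.linspace(0, 1, 20)
        matrix = np.column_stack([2 * t + 1, -3 * t + 5])
        _, ratios = pca_decompose(matrix)
        assert ratios[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_splits_variance(self):
        rng = np.random.default_rng(11)
        matrix = rng.normal(size=(10_000, 2))
        _, ratios = pca_decompose(matrix)
        assert ratios[0] == pytest.approx(0.5, abs=0.02)
        assert ratios[1] == pytest.approx(0.5, abs=0.02)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(12)
        matrix = rng.normal(size=(15, 6))
        components, _ = pca_decompose(matrix)
        centered = matrix - matrix.mean(axis=0)
        recon = centered @ components.T @ components
        assert np.allclose(recon, centered, atol=1e-9)

    def test_sign_convention(self):
        rng = np.random.default_rng(13)
        components, _ = pca_decompose(rng.normal(size=(30, 5)))
        for row in components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca_decompose([[1.0, 2.0]])


def records_for(feature_sets):
    """feature_sets: {(rarefaction_id, model): iterable of features}"""
    return [
        SelectionRecord(rid, model, frozenset(features))
        for (rid, model), features in feature_sets.items()
    ]


class TestConsensusSelect:
    def test_unanimous_feature_selected(self):
        recs = records_for(
            {(r, m): {"X"} for r in range(1, 11) for m in ("svc", "lr")}
        )
        assert consensus_select(recs, 10) == {"X"}

    def test_single_model_everywhere_not_selected(self):
        recs = records_for({(r, "svc"): {"X"} for r in range(1, 11)})
        recs += records_for({(r, "lr"): set() for r in range(1, 11)})
        assert consensus_select(recs, 10) == set()

    def test_exactly_half_is_selected_and_under_half_is_not(self):
        def agree_in(k):
            recs = records_for(
                {(r, m): {"X"} for r in range(1, k + 1) for m in ("svc", "lr")}
            )
            recs += records_for({(r, "svc"): {"X"} for r in range(k + 1, 11)})
            return recs

        assert consensus_select(agree_in(5), 10) == {"X"}
        assert consensus_select(agree_in(4), 10) == set()

    def test_unknown_model_tag_rejected(self):
        recs = [SelectionRecord(1, "rf", frozenset({"X"}))]
        with pytest.raises(ValueError):
            consensus_select(recs, 10)

    def test_monotone_in_added_records(self):
        rng = np.random.default_rng(14)
        recs = []
        features = [f"f{i}" for i in range(6)]
        selected_before = set()
        for step in range(40):
            rid = int(rng.integers(1, 11))
            model = ("svc", "lr")[int(rng.integers(0, 2))]
            chosen = {f for f in features if rng.random() < 0.4}
            recs.append(SelectionRecord(rid, model, frozenset(chosen)))
            selected_now = consensus_select(recs, 10)
            assert selected_before <= selected_now
            selected_before = selected_now
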