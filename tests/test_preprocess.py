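import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirlink import (
    background_correct,
    bh_adjust,
    moderated_t_test,
    quantile_normalize,
    select_de,
)
from mirlink.preprocess import PreprocessError, ZeroVarianceWarning, fit_variance_prior

from conftest import make_matrix


def bh_oracle(pvals):
    """Brute-force BH adjusted p: the smallest level q at which the step-up
    procedure rejects the hypothesis."""
    pvals = list(pvals)
    m = len(pvals)
    candidates = sorted({p * m / rank for rank, p in
                         enumerate(sorted(pvals), start=1)} | {1.0})

    def rejected_at(q):
        ordered = sorted(pvals)
        k = 0
        for rank, p in enumerate(ordered, start=1):
            if p <= rank * q / m:
                k = rank
        return set() if k == 0 else {i for i, p in enumerate(pvals) if p <= ordered[k - 1]}

    adj = []
    for i in range(m):
        levels = [q for q in candidates if i in rejected_at(q)]
        adj.append(min(levels) if levels else 1.0)
    return adj


class TestBackgroundCorrect:
    def test_direct_arithmetic(self):
        matrix = make_matrix([[100.0, 100.0, 100.0, 100.0]])
        out = background_correct(matrix, background=30.0, floor=0.5, offset=16.0)
        assert np.allclose(out.values.to_numpy(), 86.0)

    def test_identity_case(self):
        matrix = make_matrix([[5.0, 7.0, 9.0, 11.0]])
        out = background_correct(matrix, background=0.0, floor=0.0, offset=0.0)
        assert out.values.equals(matrix.values)

    def test_floor_saturation(self):
        matrix = make_matrix([[1.0, 2.0, 3.0, 4.0]])
        out = background_correct(matrix, background=10.0, floor=0.5, offset=16.0)
        assert np.allclose(out.values.to_numpy(), 16.5)

    def test_rejects_negative_floor(self):
        matrix = make_matrix([[1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(PreprocessError):
            background_correct(matrix, floor=-1.0)

    def test_rejects_negative_input(self):
        matrix = make_matrix([[-1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(PreprocessError):
            background_correct(matrix)


class TestQuantileNormalize:
    def test_hand_example(self):
        # two distinct column profiles, duplicated to satisfy the
        # replicate-count invariant; the cross-column order-statistic means
        # are unchanged by duplication
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        matrix = make_matrix(np.column_stack([a, b, a, b]))
        out = quantile_normalize(matrix).values.to_numpy()
        expected = np.tile([[1.5], [3.0], [4.5]], (1, 4))
        assert np.allclose(out, expected)

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0, 5.0])
        matrix = make_matrix(np.column_stack([col] * 4))
        out = quantile_normalize(matrix)
        assert np.allclose(out.values.to_numpy(), matrix.values.to_numpy())

    def test_column_means_equal_without_ties(self, rng):
        vals = rng.normal(8, 2, (50, 6))  # continuous draws: no ties
        once = quantile_normalize(make_matrix(vals))
        means = once.values.to_numpy().mean(axis=0)
        assert np.allclose(means, means[0])
        cols = np.sort(once.values.to_numpy(), axis=0)
        assert np.allclose(cols, cols[:, [0]])  # identical multisets

    def test_idempotent_on_tie_free_data(self, rng):
        vals = rng.normal(8, 2, (50, 6))
        once = quantile_normalize(make_matrix(vals))
        twice = quantile_normalize(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)

    def test_near_idempotent_with_ties(self, rng):
        # rank-averaging of ties perturbs the reference distribution, so
        # idempotence is only approximate on tied data
        vals = rng.normal(8, 2, (50, 6))
        vals[10:15, 2] = vals[10, 2]
        once = quantile_normalize(make_matrix(vals))
        twice = quantile_normalize(once)
        diff = np.abs(once.values.to_numpy() - twice.values.to_numpy())
        assert diff.max() < 0.1

    def test_duplicated_column_is_identity(self):
        vals = np.array([[1.0], [5.0], [3.0]])
        matrix = make_matrix(np.hstack([vals] * 4))
        out = quantile_normalize(matrix)
        assert np.allclose(out.values.to_numpy(), matrix.values.to_numpy())


class TestBHAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_capped(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(PreprocessError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_on_permutations(self):
        base = [0.001, 0.008, 0.039, 0.041, 0.2, 0.9]
        for perm in itertools.permutations(base):
            assert np.allclose(bh_adjust(list(perm)), bh_oracle(perm), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), adj)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_properties_hold_for_arbitrary_pvalues(self, pvals):
        adj = bh_adjust(pvals)
        assert ((adj >= np.asarray(pvals) - 1e-12) & (adj <= 1.0)).all()
        # adjusted values preserve the ordering of the raw p-values
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestModeratedT:
    def test_null_feature_has_zero_t_unit_p(self):
        vals = np.array(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
             [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]]
        )
        res = moderated_t_test(make_matrix(vals))
        assert res.loc[0, "t_stat"] == pytest.approx(0.0)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_prior_df_zero_matches_classical_t(self, rng):
        vals = rng.normal(8, 1, (5, 6))
        vals[:2, 3:] += 2.0
        matrix = make_matrix(vals)
        res = moderated_t_test(matrix, prior_df=0)
        for k in range(5):
            t_ref, p_ref = stats.ttest_ind(vals[k, 3:], vals[k, :3], equal_var=True)
            assert res.loc[k, "t_stat"] == pytest.approx(t_ref, abs=1e-10)
            assert res.loc[k, "p_value"] == pytest.approx(p_ref, abs=1e-10)

    def test_infinite_prior_gives_pooled_z(self, rng):
        vals = rng.normal(8, 1, (50, 6))
        res = moderated_t_test(make_matrix(vals), prior_df=np.inf)
        s2 = np.array(
            [
                np.var(vals[k, :3], ddof=1) * 2 / 4 + np.var(vals[k, 3:], ddof=1) * 2 / 4
                for k in range(50)
            ]
        )
        pooled = s2.mean()
        diff = vals[:, 3:].mean(axis=1) - vals[:, :3].mean(axis=1)
        z_ref = diff / np.sqrt(pooled * (2 / 3))
        assert np.allclose(res["t_stat"].to_numpy(), z_ref)

    def test_moderation_shrinks_toward_prior(self, rng):
        vals = rng.normal(8, 1, (200, 6))
        mod = moderated_t_test(make_matrix(vals))
        raw = moderated_t_test(make_matrix(vals), prior_df=0)
        # moderated |t| is less extreme than classical |t| for the most
        # variable features and more extreme for the least variable ones
        assert np.std(mod["t_stat"]) < np.std(raw["t_stat"]) * 1.5

    def test_all_zero_variance_warns_and_falls_back(self):
        vals = np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]])
        with pytest.warns(ZeroVarianceWarning):
            res = moderated_t_test(make_matrix(vals))
        assert np.isinf(res.loc[0, "t_stat"])

    def test_type_i_error_controlled_under_null(self):
        fracs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            vals = r.normal(8, 1, (500, 6))
            res = moderated_t_test(make_matrix(vals))
            fracs.append((res["adj_p"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_planted_de_recovery(self):
        recalls = []
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            vals = r.normal(8, 1, (200, 6)) * 0 + r.normal(8, 1, (200, 1))
            vals = vals + r.normal(0, 0.5, (200, 6))
            de_idx = np.arange(50)
            direction = np.where(r.random(50) < 0.5, 1.0, -1.0)
            vals[de_idx, 3:] += (2.0 * direction)[:, None]
            res = moderated_t_test(make_matrix(vals))
            picked = set(select_de(res, 0.05).all)
            recalls.append(len(picked & {f"f{i}" for i in de_idx}) / 50)
        assert np.mean(recalls) >= 0.9


class TestSelectDE:
    def test_empty_results(self):
        import pandas as pd

        empty = pd.DataFrame(columns=["feature_id", "adj_p", "direction"])
        assert select_de(empty).all == []

    def test_alpha_zero_empty(self, rng):
        res = moderated_t_test(make_matrix(rng.normal(8, 1, (10, 6))))
        assert select_de(res, alpha=0.0).all == []

    def test_partition_consistent_with_direction(self, rng):
        vals = rng.normal(8, 0.5, (100, 6))
        vals[:20, 3:] += 4.0
        vals[20:40, 3:] -= 4.0
        sel = select_de(moderated_t_test(make_matrix(vals)), 0.05)
        assert set(sel.all) == set(sel.up) | set(sel.down)
        assert set(sel.up).isdisjoint(sel.down)
        assert {f"f{i}" for i in range(20)} <= set(sel.up)
        assert {f"f{i}" for i in range(20, 40)} <= set(sel.down)


class TestVariancePrior:
    def test_no_excess_dispersion_pools_fully(self, rng):
        # chi-square dispersion alone: prior df should be infinite
        s2 = stats.chi2.rvs(4, size=5000, random_state=1) / 4
        prior = fit_variance_prior(s2, 4)
        assert np.isinf(prior.prior_df) or prior.prior_df > 50

    def test_heterogeneous_variances_give_finite_prior(self, rng):
        sigma2 = stats.invgamma.rvs(3, scale=2, size=2000, random_state=2)
        s2 = sigma2 * stats.chi2.rvs(4, size=2000, random_state=3) / 4
        prior = fit_variance_prior(s2, 4)
        assert np.isfinite(prior.prior_df)
        assert prior.prior_var > 0
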