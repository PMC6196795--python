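import numpy as np
import pytest
from scipy import stats

from mirlink import (
    SimulationConfig,
    association_scores,
    fit_pls,
    generate_dataset,
    score_candidate_pairs,
)
from mirlink.pls import PLSError, ZeroVarianceError
from mirlink.targets import CandidatePairSet


class TestFitPLS:
    def test_perfect_single_predictor_fit_has_zero_residuals(self, rng):
        x = rng.normal(0, 1, (6, 1))
        model = fit_pls(x, x.copy(), v=1)
        assert np.allclose(model.residuals, 0.0, atol=1e-12)

    def test_component_coefficients_match_ols_oracle(self, rng):
        x = rng.normal(0, 1, (6, 3))
        y = rng.normal(0, 1, (6, 2))
        model = fit_pls(x, y, v=2)
        ys = (y - y.mean(0)) / y.std(0, ddof=1)
        for i in range(2):
            resid = ys[:, i].copy()
            for l in range(2):
                t = model.scores[i, l]
                beta_oracle = np.linalg.lstsq(t[:, None], resid, rcond=None)[0][0]
                assert model.y_loadings[i, l] == pytest.approx(beta_oracle, abs=1e-10)
                resid = resid - model.y_loadings[i, l] * t

    def test_latent_components_orthogonal(self, rng):
        x = rng.normal(0, 1, (6, 4))
        y = rng.normal(0, 1, (6, 3))
        model = fit_pls(x, y, v=3)
        for i in range(3):
            for a in range(3):
                for b in range(a + 1, 3):
                    ta, tb = model.scores[i, a], model.scores[i, b]
                    denom = np.linalg.norm(ta) * np.linalg.norm(tb)
                    if denom > 0:
                        assert abs(ta @ tb) / denom < 1e-8

    def test_rejects_v_at_least_n(self, rng):
        x = rng.normal(0, 1, (4, 2))
        with pytest.raises(PLSError):
            fit_pls(x, x, v=4)

    def test_rejects_zero_variance_column(self, rng):
        x = rng.normal(0, 1, (6, 3))
        x[:, 1] = 7.0
        with pytest.raises(ZeroVarianceError):
            fit_pls(x, rng.normal(0, 1, (6, 2)), v=2)

    def test_joint_coefficients_match_sklearn(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        x = rng.normal(0, 1, (8, 4))
        y = rng.normal(0, 1, (8, 1))
        model = fit_pls(x, y, v=3)
        ours = model.coefficients()[0]
        ref = PLSRegression(n_components=3, scale=True).fit(x, y)
        theirs = ref.coef_.ravel() * x.std(0, ddof=1) / y.std(0, ddof=1)
        assert np.allclose(ours, theirs, atol=1e-8)


class TestAssociationScores:
    @pytest.mark.parametrize("mode", ["pairwise", "joint"])
    def test_single_predictor_equals_pearson(self, mode, rng):
        for _ in range(20):
            x = rng.normal(0, 1, (6, 1))
            y = rng.normal(0, 1, (6, 3))
            model = fit_pls(x, y, v=1)
            assoc = association_scores(model, x, y, mode=mode)
            for i in range(3):
                r = stats.pearsonr(x[:, 0], y[:, i]).statistic
                assert assoc.scores.iloc[i, 0] == pytest.approx(r, abs=1e-10)

    @pytest.mark.parametrize("mode", ["pairwise", "joint"])
    def test_scale_invariance_of_responses(self, mode, rng):
        x = rng.normal(0, 1, (6, 4))
        y = rng.normal(0, 1, (6, 3))
        y2 = y.copy()
        y2[:, 1] *= 13.7
        a = association_scores(fit_pls(x, y, v=2), x, y, mode=mode)
        b = association_scores(fit_pls(x, y2, v=2), x, y2, mode=mode)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-10)

    @pytest.mark.parametrize("mode", ["pairwise", "joint"])
    def test_sign_flip_of_predictor_column(self, mode, rng):
        x = rng.normal(0, 1, (6, 4))
        y = rng.normal(0, 1, (6, 3))
        x2 = x.copy()
        x2[:, 2] *= -1
        a = association_scores(fit_pls(x, y, v=2), x, y, mode=mode).scores.to_numpy()
        b = association_scores(fit_pls(x2, y, v=2), x2, y, mode=mode).scores.to_numpy()
        flipped = a.copy()
        flipped[:, 2] *= -1
        assert np.allclose(b, flipped, atol=1e-10)

    def test_pairwise_null_matches_closed_form_mean(self):
        """At N=6 the null |r| has mean 3/8 under independence: the density
        of r is (3/4)(1-r^2), so E|r| = 0.375."""
        means = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, (6, 5))
            y = r.normal(0, 1, (6, 10))
            assoc = association_scores(fit_pls(x, y, v=2), x, y)
            means.append(np.abs(assoc.scores.to_numpy()).mean())
        assert np.mean(means) == pytest.approx(0.375, abs=0.02)

    def test_joint_mode_null_scores_are_shrunk(self):
        """With many collinear predictors the joint coefficients are spread:
        their null magnitude is far below the pairwise correlation scale."""
        means = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, (6, 30))
            y = r.normal(0, 1, (6, 10))
            assoc = association_scores(fit_pls(x, y, v=3), x, y, mode="joint")
            means.append(np.abs(assoc.scores.to_numpy()).mean())
        assert np.mean(means) < 0.2

    def test_planted_repression_scores_below_edge_threshold(self):
        """A strong planted regulation (strength 1, low noise) produces a
        pairwise score below -0.8."""
        config = SimulationConfig(
            n_mirna=10, n_mrna=50, n_planted_edges=5,
            regulation_strength=1.0, noise_sd=0.1, seed=5,
        )
        mirna, mrna, _, truth = generate_dataset(config)
        model = fit_pls(mirna, mrna, v=3)
        assoc = association_scores(model, mirna, mrna)
        targets = [m for _, m, _ in truth.planted_edges]
        for mi_id, mr_id, _ in truth.planted_edges:
            if targets.count(mr_id) > 1:
                continue
            assert assoc.score(mi_id, mr_id) < -0.8


class TestScoreCandidatePairs:
    def test_empty_candidates(self, small_dataset):
        mirna, mrna, _, _ = small_dataset
        model = fit_pls(mirna, mrna, v=2)
        assoc = association_scores(model, mirna, mrna)
        assert len(score_candidate_pairs(assoc, CandidatePairSet())) == 0

    def test_all_pairs_scored(self, small_dataset):
        mirna, mrna, _, _ = small_dataset
        model = fit_pls(mirna, mrna, v=2)
        assoc = association_scores(model, mirna, mrna)
        full = CandidatePairSet(
            {(m, g) for m in mirna.feature_ids for g in mrna.feature_ids}
        )
        assert len(score_candidate_pairs(assoc, full)) == 8 * 40

    def test_unknown_id_rejected(self, small_dataset):
        mirna, mrna, _, _ = small_dataset
        model = fit_pls(mirna, mrna, v=2)
        assoc = association_scores(model, mirna, mrna)
        with pytest.raises(PLSError):
            score_candidate_pairs(assoc, CandidatePairSet({("nope", "mRNA-0001")}))

    def test_non_candidates_never_scored(self, small_dataset):
        mirna, mrna, candidates, _ = small_dataset
        model = fit_pls(mirna, mrna, v=2)
        assoc = association_scores(model, mirna, mrna)
        scored = score_candidate_pairs(assoc, candidates)
        assert len(scored) == len(candidates)
        assert set(zip(scored.mirna_id, scored.mrna_id)) == candidates.pairs


class TestParameterRecovery:
    def test_planted_edges_rank_high_by_absolute_score(self):
        """Ranking all miRNA-mRNA pairs by |score| puts the planted edges'
        median rank inside the top decile."""
        for seed in range(5):
            config = SimulationConfig(seed=seed)
            mirna, mrna, _, truth = generate_dataset(config)
            model = fit_pls(mirna, mrna, v=3)
            assoc = association_scores(model, mirna, mrna)
            flat = np.abs(assoc.scores.to_numpy()).ravel()
            order = np.argsort(-flat)
            rank_of = np.empty_like(order)
            rank_of[order] = np.arange(1, flat.size + 1)
            col = {m: k for k, m in enumerate(assoc.scores.columns)}
            row = {g: k for k, g in enumerate(assoc.scores.index)}
            ranks = [
                rank_of[row[g] * assoc.scores.shape[1] + col[m]]
                for m, g, _ in truth.planted_edges
            ]
            assert np.median(ranks) <= 0.1 * flat.size
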