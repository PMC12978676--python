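import numpy as np
import pandas as pd
import pytest
from scipy import stats

from restspeech.inference import (comparison_anova, group_slopes, knn_classify,
                                  knn_k, moderated_regression, permutation_p,
                                  simple_regression, slope_diff_z,
                                  stratified_split, welch_t)
from restspeech.rsa import label_pairs


def welch_oracle(a, b):
    """Textbook Welch statistic and Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_worked_example(self):
        res = welch_t([1.0, 2, 3], [4.0, 5, 6])
        assert res.statistic == pytest.approx(-3.674235, abs=1e-6)
        assert res.df == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=rng.integers(5, 30))
        b = rng.normal(0.3, 2, size=rng.integers(5, 30))
        res = welch_t(a, b)
        t, df = welch_oracle(a, b)
        assert res.statistic == pytest.approx(t, rel=1e-10)
        assert res.df == pytest.approx(df, rel=1e-10)
        assert min(len(a), len(b)) - 1 <= res.df <= len(a) + len(b) - 2

    def test_degenerate_equal_constant_samples(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.statistic == 0.0 and res.p == 1.0


class TestComparisonAnova:
    @staticmethod
    def _pairs(n_young, n_old, values=None, seed=0):
        groups = {f"y{i:02d}": "younger" for i in range(n_young)}
        groups |= {f"o{i:02d}": "older" for i in range(n_old)}
        table = label_pairs(list(groups), groups)
        rng = np.random.default_rng(seed)
        table["m"] = rng.normal(size=len(table)) if values is None else values
        col = table["m"]
        table["m_z"] = (col - col.mean()) / col.std(ddof=1)
        return table

    def test_sixty_participants_residual_df(self):
        table = self._pairs(36, 24)
        res, _ = comparison_anova(table, "m")
        assert len(table) == 1770
        assert res.df == 1767

    def test_matches_sums_of_squares_oracle(self):
        for seed in range(10):
            table = self._pairs(8, 6, seed=seed)
            res, _ = comparison_anova(table, "m")
            y = table["m_z"].to_numpy()
            codes = table["comparison_group"].to_numpy()
            grand = y.mean()
            ssb = sum((codes == c).sum() * (y[codes == c].mean() - grand) ** 2
                      for c in (-0.5, 0.0, 0.5))
            sse = sum(((y[codes == c] - y[codes == c].mean()) ** 2).sum()
                      for c in (-0.5, 0.0, 0.5))
            f = (ssb / 2) / (sse / (len(y) - 3))
            assert res.statistic == pytest.approx(f, rel=1e-10)

    def test_null_rejection_rate_near_alpha(self):
        rej = 0
        n_sims = 200
        for seed in range(n_sims):
            res, _ = comparison_anova(self._pairs(7, 5, seed=seed), "m")
            rej += res.p < 0.05
        assert rej / n_sims == pytest.approx(0.05, abs=0.05)

    def test_separated_groups_show_in_followups(self):
        table = self._pairs(8, 6)
        rng = np.random.default_rng(1)
        codes = table["comparison_group"].to_numpy()
        table["m"] = np.where(codes == 0.5, 1.0, 0.0) + rng.normal(0, 0.1,
                                                                   len(table))
        table["m_z"] = ((table["m"] - table["m"].mean())
                        / table["m"].std(ddof=1))
        res, follow = comparison_anova(table, "m")
        assert res.p < 1e-6
        follow = follow.set_index(["group1", "group2"])
        assert follow.loc[("between", "within_older"), "reject"]
        assert follow.loc[("between", "within_younger"), "reject"]
        assert not follow.loc[("within_older", "within_younger"), "reject"]

    def test_empty_level_rejected(self):
        groups = {"a": "younger", "b": "younger", "c": "younger"}
        table = label_pairs(list(groups), groups)
        table["m"] = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError):
            comparison_anova(table, "m")


class TestKnn:
    @pytest.mark.parametrize("n,k", [(45, 6), (100, 10), (20, 4), (1, 1)])
    def test_square_root_rule(self, n, k):
        assert knn_k(n) == k

    def test_separated_clusters_classified_perfectly(self, rng):
        ids = [f"p{i}" for i in range(40)]
        groups = pd.Series(["younger"] * 20 + ["older"] * 20, index=ids)
        feats = {}
        for i, pid in enumerate(ids):
            center = 0.0 if i < 20 else 10.0
            feats[pid] = rng.normal(center, 1.0, size=5)
        res = knn_classify(feats, groups, 0.7, seed=1)
        assert res.accuracy == 1.0
        assert res.confusion.to_numpy().sum() == len(res.test_ids)

    def test_null_labels_near_base_rate(self, rng):
        accs = []
        for rep in range(60):
            ids = [f"p{i}" for i in range(30)]
            labels = ["younger"] * 18 + ["older"] * 12
            rng.shuffle(labels)
            groups = pd.Series(labels, index=ids)
            feats = {pid: rng.normal(size=4) for pid in ids}
            accs.append(knn_classify(feats, groups, 0.7, seed=rep).accuracy)
        base_rate = 18 / 30
        assert np.mean(accs) == pytest.approx(base_rate, abs=0.1)

    def test_same_seed_same_split_and_confusion(self, rng):
        ids = [f"p{i}" for i in range(20)]
        groups = pd.Series(["younger"] * 12 + ["older"] * 8, index=ids)
        feats = {pid: rng.normal(size=3) for pid in ids}
        r1 = knn_classify(feats, groups, 0.7, seed=9)
        r2 = knn_classify(feats, groups, 0.7, seed=9)
        assert r1.train_ids == r2.train_ids
        assert r1.confusion.equals(r2.confusion)

    def test_k_follows_training_set_size(self, rng):
        ids = [f"p{i}" for i in range(40)]
        groups = pd.Series(["younger"] * 24 + ["older"] * 16, index=ids)
        feats = {pid: rng.normal(size=3) for pid in ids}
        res = knn_classify(feats, groups, 0.7, seed=0)
        assert res.k == knn_k(len(res.train_ids))

    def test_stratified_split_keeps_both_classes(self, rng):
        ids = [f"p{i}" for i in range(30)]
        groups = pd.Series(["younger"] * 25 + ["older"] * 5, index=ids)
        train, test = stratified_split(groups, 0.7, np.random.default_rng(0))
        assert set(groups[test]) == {"younger", "older"}
        assert len(train) + len(test) == 30

    def test_agreement_with_sklearn_on_odd_k(self, rng):
        # independent cross-check: with odd k there are no vote ties, so the
        # hand-rolled classifier must agree with sklearn's
        from sklearn.neighbors import KNeighborsClassifier
        xtr = rng.normal(size=(25, 4))   # 25 -> k = 5, odd
        ytr = np.array(["a"] * 13 + ["b"] * 12)
        xte = rng.normal(size=(10, 4))
        ids = [f"t{i}" for i in range(25)] + [f"s{i}" for i in range(10)]
        sk = KNeighborsClassifier(n_neighbors=5).fit(xtr, ytr)
        from scipy.spatial.distance import cdist
        order = np.argsort(cdist(xte, xtr), axis=1)
        mine = []
        for row in order:
            votes = ytr[row[:5]]
            counts = {lab: (votes == lab).sum() for lab in ("a", "b")}
            mine.append(max(counts, key=counts.get))
        np.testing.assert_array_equal(mine, sk.predict(xte))


class TestRegressions:
    def test_perfect_predictor_beta_one(self, rng):
        x = rng.normal(size=30)
        res = simple_regression(x, x)
        assert res.betas[1] == pytest.approx(1.0, abs=1e-10)

    def test_moderated_regression_against_statsmodels(self, rng):
        import statsmodels.api as sm
        y = rng.normal(size=40)
        x = rng.normal(size=40)
        g = np.repeat([-0.5, 0.5], 20)
        res = moderated_regression(y, x, g)
        ys = (y - y.mean()) / y.std(ddof=1)
        xs = (x - x.mean()) / x.std(ddof=1)
        design = sm.add_constant(np.column_stack([g, xs, g * xs]))
        fit = sm.OLS(ys, design).fit()
        np.testing.assert_allclose(res.betas, fit.params, rtol=1e-8)
        np.testing.assert_allclose(res.ses, fit.bse, rtol=1e-8)
        np.testing.assert_allclose(res.p, fit.pvalues, rtol=1e-8)

    def test_null_interaction_rejection_calibrated(self):
        rej = 0
        n_sims = 500
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=60)
            x = rng.normal(size=60)
            g = np.repeat([-0.5, 0.5], 30)
            res = moderated_regression(y, x, g)
            rej += res.p[3] < 0.05
        assert rej / n_sims == pytest.approx(0.05, abs=0.02)

    def test_group_slopes_reconcile_with_pooled_interaction(self, rng):
        # with shared standardization, slope_g = beta_pred + code_g * beta_int
        y = rng.normal(size=50)
        x = rng.normal(size=50)
        g = np.repeat([-0.5, 0.5], 25)
        pooled = moderated_regression(y, x, g)
        ys = (y - y.mean()) / y.std(ddof=1)
        xs = (x - x.mean()) / x.std(ddof=1)
        for code, mask in ((-0.5, g == -0.5), (0.5, g == 0.5)):
            b = np.polyfit(xs[mask], ys[mask], 1)[0]
            assert b == pytest.approx(pooled.betas[2] + code * pooled.betas[3],
                                      abs=1e-10)

    def test_group_slopes_recover_construction(self, rng):
        x = rng.normal(size=60)
        groups = np.array(["younger"] * 30 + ["older"] * 30)
        y = np.where(groups == "younger", x, rng.normal(size=60))
        slopes = group_slopes(y, x, groups)
        assert slopes["younger"].betas[1] == pytest.approx(1.0, abs=1e-8)
        assert abs(slopes["older"].betas[1]) < 0.5

    def test_rank_deficiency_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            moderated_regression(np.arange(10.0), np.arange(10.0),
                                 np.zeros(10))

    def test_empty_group_raises(self, rng):
        with pytest.raises(ValueError):
            group_slopes(rng.normal(size=6), rng.normal(size=6),
                         np.array(["younger"] * 4 + ["older"] * 2))


class TestSlopeDiffZ:
    def test_equal_slopes_give_zero(self):
        res = slope_diff_z(0.5, 0.1, 0.5, 0.2)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_worked_example(self):
        res = slope_diff_z(1.0, 0.3, 0.0, 0.4)
        assert res.statistic == pytest.approx(2.0)
        assert res.p == pytest.approx(0.0455, abs=1e-3)

    def test_antisymmetry(self):
        a = slope_diff_z(0.8, 0.2, 0.3, 0.25)
        b = slope_diff_z(0.3, 0.25, 0.8, 0.2)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            slope_diff_z(1.0, 0.0, 0.5, 0.1)


class TestPermutationP:
    @staticmethod
    def _fit_factory(x, g):
        def fit(scores):
            return moderated_regression(scores.to_numpy(), x, g)
        return fit

    def test_add_one_convention_lower_bound(self, rng):
        # outcome perfectly tied to predictor: no permutation beats it
        x = rng.normal(size=30)
        g = np.repeat([-0.5, 0.5], 15)
        scores = pd.Series(x + 0.01 * rng.normal(size=30),
                           index=[f"p{i}" for i in range(30)])
        p = permutation_p(self._fit_factory(x, g), scores, B=1000, seed=0)
        assert p[2] == pytest.approx(1 / 1001, abs=1e-9)

    def test_same_seed_identical_p(self, rng):
        x = rng.normal(size=20)
        g = np.repeat([-0.5, 0.5], 10)
        scores = pd.Series(rng.normal(size=20),
                           index=[f"p{i}" for i in range(20)])
        fit = self._fit_factory(x, g)
        np.testing.assert_array_equal(permutation_p(fit, scores, B=99, seed=5),
                                      permutation_p(fit, scores, B=99, seed=5))

    def test_parametric_and_permutation_p_track_each_other(self):
        # Gaussian score-level designs: the two p-values agree in rank order
        pp, pa = [], []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=24)
            g = np.repeat([-0.5, 0.5], 12)
            scores = pd.Series(rng.normal(size=24) + 0.4 * x,
                               index=[f"p{i}" for i in range(24)])
            fit = self._fit_factory(x, g)
            res = fit(scores)
            pa.append(res.p[2])
            pp.append(permutation_p(fit, scores, B=200, seed=seed)[2])
        rho = stats.spearmanr(pa, pp).statistic
        assert rho > 0.9
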