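"""Statistical battery for the group-level and dissimilarity-level analyses.

Welch two-sample t-tests for group effects; one-way comparison-group ANOVAs
with Tukey HSD follow-ups over pairwise dissimilarities; stratified k-NN
group classification from connectivity features (k = floor(sqrt(n_train)));
moderated OLS regressions (outcome ~ group + predictor + group x predictor,
continuous variables standardized, group codes passed through on their
+-0.5 scale); per-group follow-up slopes with a normal z-test on the slope
difference; and Mantel-style permutation p-values obtained by permuting
participant-level outcomes (rebuilding pairwise dissimilarities for
pair-level designs) and refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .rsa import BETWEEN, WITHIN_OLDER, WITHIN_YOUNGER


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    estimate: float | None = None
    se: float | None = None


@dataclass
class RegressionResult:
    terms: list[str]
    betas: np.ndarray
    ses: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n: int
    p_perm: np.ndarray | None = None

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        out = {"term": name, "beta": float(self.betas[i]), "se": float(self.ses[i]),
               "t": float(self.t[i]), "p": float(self.p[i])}
        if self.p_perm is not None:
            out["p_perm"] = float(self.p_perm[i])
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"term": self.terms, "beta": self.betas, "se": self.ses,
                           "t": self.t, "p": self.p})
        if self.p_perm is not None:
            df["p_perm"] = self.p_perm
        return df


@dataclass
class ClassificationResult:
    k: int
    confusion: pd.DataFrame        # rows = true, cols = predicted
    accuracy: float
    train_ids: list[str]
    test_ids: list[str]


def welch_t(a, b) -> TestResult:
    """Unequal-variance two-sample t-test with Satterthwaite df, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, float(len(a) + len(b) - 2), 1.0,
                              estimate=0.0, se=0.0)
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    diff = float(a.mean() - b.mean())
    se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      estimate=diff, se=se)


_CODE_NAMES = {WITHIN_YOUNGER: "within_younger", WITHIN_OLDER: "within_older",
               BETWEEN: "between"}


def comparison_anova(pairs: pd.DataFrame, measure: str
                     ) -> tuple[TestResult, pd.DataFrame]:
    """One-way fixed-effects ANOVA of a standardized dissimilarity on the
    3-level comparison group, with Tukey HSD pairwise follow-ups.

    Residual df is (number of pairs) - 3.
    """
    col = measure + "_z" if measure + "_z" in pairs.columns else measure
    y = pairs[col].to_numpy(dtype=float)
    codes = pairs["comparison_group"].to_numpy(dtype=float)
    levels = [WITHIN_YOUNGER, WITHIN_OLDER, BETWEEN]
    samples = [y[codes == lv] for lv in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("all three comparison groups must be non-empty")
    grand = y.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df1, df2 = 2, len(y) - 3
    f = (ssb / df1) / (sse / df2)
    p = float(stats.f.sf(f, df1, df2))
    labels = np.array([_CODE_NAMES[c] for c in codes])
    tukey = pairwise_tukeyhsd(y, labels)
    follow = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return TestResult(float(f), float(df2), p), follow


def knn_k(n_train: int) -> int:
    """k = floor(sqrt(n_train)), at least 1 (the square-root rule)."""
    if n_train < 1:
        raise ValueError("training set must be non-empty")
    return max(int(np.floor(np.sqrt(n_train))), 1)


def stratified_split(groups: pd.Series, train_fraction: float,
                     rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Seeded stratified train/test partition of participant ids."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    train, test = [], []
    for g in sorted(groups.unique()):
        ids = sorted(groups.index[groups == g].tolist())
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
    if not test or not train:
        raise ValueError("split left an empty partition")
    test_groups = set(groups[t] for t in test)
    if test_groups != set(groups.unique()):
        raise ValueError("test set is missing a class after stratification")
    return sorted(train), sorted(test)


def knn_classify(features: dict[str, np.ndarray], groups: pd.Series,
                 train_fraction: float = 0.7, seed: int = 0) -> ClassificationResult:
    """Stratified-split k-NN classification of group membership.

    Majority vote over the k Euclidean-nearest training points, with
    k = floor(sqrt(n_train)); vote ties are broken by the single nearest
    neighbor's label.
    """
    rng = np.random.default_rng(seed)
    ids = list(features)
    groups = groups.loc[ids]
    train_ids, test_ids = stratified_split(groups, train_fraction, rng)
    k = knn_k(len(train_ids))
    xtr = np.vstack([features[i] for i in train_ids])
    xte = np.vstack([features[i] for i in test_ids])
    ytr = groups.loc[train_ids].to_numpy()
    yte = groups.loc[test_ids].to_numpy()
    dist = cdist(xte, xtr, metric="euclidean")
    order = np.argsort(dist, axis=1, kind="stable")
    labels = sorted(groups.unique())
    preds = []
    for row in order:
        votes = ytr[row[:k]]
        counts = {lab: int((votes == lab).sum()) for lab in labels}
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        preds.append(winners[0] if len(winners) == 1 else ytr[row[0]])
    preds = np.array(preds)
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    for t, p in zip(yte, preds):
        confusion.loc[t, p] += 1
    acc = float((preds == yte).mean())
    return ClassificationResult(k=k, confusion=confusion, accuracy=acc,
                                train_ids=train_ids, test_ids=test_ids)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS betas and standard errors; raises on rank deficiency."""
    n, p = x.shape
    q, r = np.linalg.qr(x)
    if np.min(np.abs(np.diag(r))) < 1e-10 * np.max(np.abs(np.diag(r))):
        raise np.linalg.LinAlgError("rank-deficient design")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - x @ beta
    sigma2 = (resid @ resid) / (n - p)
    rinv = np.linalg.inv(r)
    se = np.sqrt(sigma2 * (rinv @ rinv.T).diagonal())
    return beta, se


def moderated_regression(outcome, predictor, group_code,
                         predictor_name: str = "predictor") -> RegressionResult:
    """OLS: outcome ~ intercept + group + predictor + group x predictor.

    Continuous variables are standardized internally; the group code is used
    as supplied (+-0.5 two-group coding or -0.5/0/+0.5 comparison-group
    coding) so its betas keep their interpretable scale.
    """
    y = _standardize(np.asarray(outcome, dtype=float))
    xp = _standardize(np.asarray(predictor, dtype=float))
    g = np.asarray(group_code, dtype=float)
    if len(y) < 8:
        raise ValueError("need n >= 8 observations")
    x = np.column_stack([np.ones_like(y), g, xp, g * xp])
    beta, se = _ols(y, x)
    t = beta / se
    dfres = len(y) - x.shape[1]
    p = 2 * stats.t.sf(np.abs(t), dfres)
    terms = ["intercept", "group", predictor_name, f"group:{predictor_name}"]
    return RegressionResult(terms=terms, betas=beta, ses=se, t=t, p=p, n=len(y))


def simple_regression(outcome, predictor, predictor_name: str = "predictor"
                      ) -> RegressionResult:
    """Simple OLS on standardized variables: outcome ~ predictor."""
    y = _standardize(np.asarray(outcome, dtype=float))
    xp = _standardize(np.asarray(predictor, dtype=float))
    x = np.column_stack([np.ones_like(y), xp])
    beta, se = _ols(y, x)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), len(y) - 2)
    return RegressionResult(terms=["intercept", predictor_name], betas=beta,
                            ses=se, t=t, p=p, n=len(y))


def group_slopes(outcome, predictor, groups, predictor_name: str = "predictor"
                 ) -> dict[str, RegressionResult]:
    """Separate simple regressions per group (standardization within group)."""
    y = np.asarray(outcome, dtype=float)
    xp = np.asarray(predictor, dtype=float)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() < 4:
            raise ValueError(f"group {g!r} has n < 4")
        out[str(g)] = simple_regression(y[mask], xp[mask], predictor_name)
    return out


def slope_diff_z(b1: float, se1: float, b2: float, se2: float) -> TestResult:
    """Normal z-test for the difference of two independent regression slopes:
    z = (b1 - b2) / sqrt(se1^2 + se2^2)."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
    return TestResult(float(z), float("inf"), float(2 * stats.norm.sf(abs(z))),
                      estimate=float(b1 - b2), se=float(np.sqrt(se1**2 + se2**2)))


def permutation_p(fit, outcome_by_participant: pd.Series, B: int = 1000,
                  seed: int = 0) -> np.ndarray:
    """Permutation p-values for every term of a participant-level refit.

    ``fit(scores)`` must map a participant-indexed outcome Series to a
    RegressionResult; for pair-level designs the callable rebuilds the
    pairwise speech dissimilarities from the (permuted) scores before
    refitting, so the permutation respects the dyadic dependence structure.
    p = (1 + #{|t*| >= |t_obs|}) / (B + 1) per term.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    obs = fit(outcome_by_participant)
    t_obs = np.abs(obs.t)
    counts = np.zeros_like(t_obs)
    failures = 0
    vals = outcome_by_participant.to_numpy()
    for _ in range(B):
        perm = pd.Series(rng.permutation(vals), index=outcome_by_participant.index)
        try:
            res = fit(perm)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        counts += np.abs(res.t) >= t_obs
    used = B - failures
    if failures > 0.01 * B:
        warnings.warn(f"{failures}/{B} permutation refits failed", stacklevel=2)
    if used < 1:
        raise RuntimeError("all permutation refits failed")
    return (1.0 + counts) / (used + 1.0)
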