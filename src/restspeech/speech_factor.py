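"""Composite speech-production factor from five coded speech measures.

Five per-participant measures — mean length of utterance (MLU), verbs per
utterance, largest connected component of the speech word-graph (LCC),
repeated edges (RE), and disfluency proportion — are reduced to a single
latent factor by exploratory factor analysis: variables are standardized, a
single common factor is extracted by iterated principal-axis factoring of the
correlation matrix, a varimax rotation is applied (the identity for one
factor, executed for auditability), and regression-method (Thurstone) factor
scores are returned with sample mean zero.  The factor is signed so that the
MLU loading is positive: higher scores mean longer, more complex and more
fluent speech.

Adequacy diagnostics (Bartlett's sphericity test, Kaiser-Meyer-Olkin sampling
adequacy, variance inflation factors, Mahalanobis outlier probabilities) are
computed before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SPEECH_VARS = ["mlu", "verbs", "lcc", "re", "disfluency"]


class AdequacyError(ValueError):
    """Correlation matrix unusable for factoring (e.g., singular)."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg)
        self.trace = trace


@dataclass
class AdequacyReport:
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    kmo_overall: float
    vif: dict[str, float]
    mahalanobis_p: dict[str, float]


@dataclass
class FactorModel:
    loadings: pd.Series            # per variable
    variance_explained: float
    eigenvalues: np.ndarray        # of the correlation matrix
    n_factors_kaiser: int
    scores: pd.Series = field(default=None)  # per participant
    means: pd.Series = field(default=None)   # standardization constants
    sds: pd.Series = field(default=None)
    corr: pd.DataFrame = field(default=None)


def _check_table(measures: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SPEECH_VARS if c not in measures.columns]
    if missing:
        raise KeyError(f"speech table missing columns: {missing}")
    tab = measures[SPEECH_VARS].astype(float)
    if tab.isna().any().any():
        raise ValueError("speech table contains missing values")
    return tab


def adequacy_checks(measures: pd.DataFrame) -> AdequacyReport:
    """Bartlett sphericity, KMO, per-variable VIF, per-participant Mahalanobis p."""
    tab = _check_table(measures)
    n, p = tab.shape
    if n < 6:
        raise ValueError("need at least 6 participants for adequacy checks")
    r = np.corrcoef(tab.to_numpy(), rowvar=False)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0 or not np.isfinite(logdet):
        raise AdequacyError("singular correlation matrix")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    bart_p = float(stats.chi2.sf(chi2, df))

    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise AdequacyError("singular correlation matrix") from exc
    if np.max(np.abs(rinv)) > 1e12:
        raise AdequacyError("singular correlation matrix")
    d = np.sqrt(np.diag(rinv))
    partial = -rinv / np.outer(d, d)   # anti-image partial correlations
    off = ~np.eye(p, dtype=bool)
    kmo = float((r[off] ** 2).sum() / ((r[off] ** 2).sum() + (partial[off] ** 2).sum()))

    vif = dict(zip(SPEECH_VARS, np.diag(rinv).tolist()))

    x = tab.to_numpy()
    cov = np.cov(x, rowvar=False)
    delta = x - x.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(cov), delta)
    maha_p = dict(zip(measures.index.astype(str), stats.chi2.sf(d2, p).tolist()))

    return AdequacyReport(bartlett_chi2=float(chi2), bartlett_df=int(df),
                          bartlett_p=bart_p, kmo_overall=kmo, vif=vif,
                          mahalanobis_p=maha_p)


def _paf(r: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> tuple[np.ndarray, list[float]]:
    """Single-factor iterated principal-axis factoring of a correlation matrix."""
    p = r.shape[0]
    try:
        h = 1.0 - 1.0 / np.diag(np.linalg.inv(r))   # initial communalities: SMC
    except np.linalg.LinAlgError:
        # singular R (perfectly collinear variables): fall back to the
        # largest absolute off-diagonal correlation per variable
        off = np.abs(r - np.eye(p))
        h = off.max(axis=0)
    trace = []
    for _ in range(max_iter):
        rr = r.copy()
        np.fill_diagonal(rr, h)
        vals, vecs = np.linalg.eigh(rr)
        lam = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
        h_new = np.clip(lam**2, 0.0, 1.0)
        delta = float(np.max(np.abs(h_new - h)))
        trace.append(delta)
        h = h_new
        if delta < tol:
            return lam, trace
    raise ConvergenceError(f"communality iteration did not converge in {max_iter} steps", trace)


def varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation; identity when there is a single factor."""
    lam = np.atleast_2d(loadings.T).T
    p, k = lam.shape
    if k == 1:
        return lam.copy()
    rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        lr = lam @ rot
        u, s, vt = np.linalg.svd(
            lam.T @ (lr**3 - lr @ np.diag((lr**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return lam @ rot


def fit_speech_factor(measures: pd.DataFrame, require_adequacy: bool = False) -> FactorModel:
    """Fit the single speech factor and score participants.

    With ``require_adequacy=True`` the fit aborts when Bartlett's test is not
    significant at 0.05 or KMO falls below 0.6.
    """
    tab = _check_table(measures)
    if require_adequacy:
        rep = adequacy_checks(measures)
        if rep.bartlett_p > 0.05 or rep.kmo_overall < 0.6:
            raise AdequacyError(
                f"adequacy failed (Bartlett p={rep.bartlett_p:.3g}, KMO={rep.kmo_overall:.2f})"
            )
    means = tab.mean()
    sds = tab.std(ddof=1)
    if (sds == 0).any():
        raise AdequacyError(f"constant variable(s): {list(sds.index[sds == 0])}")
    z = (tab - means) / sds
    r = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals = np.sort(np.linalg.eigvalsh(r))[::-1]
    n_kaiser = int((eigvals > 1.0).sum())
    if n_kaiser > 1:
        warnings.warn(
            f"Kaiser criterion suggests {n_kaiser} factors; a single factor is extracted",
            stacklevel=2,
        )
    lam, _ = _paf(r)
    lam = varimax(lam)[:, 0]
    loadings = pd.Series(lam, index=SPEECH_VARS)
    if loadings["mlu"] < 0:
        loadings = -loadings
    model = FactorModel(
        loadings=loadings,
        variance_explained=float((loadings**2).sum() / len(SPEECH_VARS)),
        eigenvalues=eigvals,
        n_factors_kaiser=max(n_kaiser, 1),
        means=means,
        sds=sds,
        corr=pd.DataFrame(r, index=SPEECH_VARS, columns=SPEECH_VARS),
    )
    model.scores = score_participants(model, measures)
    return model


def score_participants(model: FactorModel, measures: pd.DataFrame) -> pd.Series:
    """Regression-method (Thurstone) factor scores: Z R^-1 loadings; mean 0."""
    tab = _check_table(measures)
    if list(model.loadings.index) != SPEECH_VARS:
        raise KeyError("model variable set does not match speech table")
    z = ((tab - model.means) / model.sds).to_numpy()
    # pinv keeps scoring defined when R is (near-)singular, e.g. noiseless data
    w = np.linalg.pinv(model.corr.to_numpy()) @ model.loadings.to_numpy()
    scores = z @ w
    scores = scores - scores.mean()   # enforce exact zero mean
    return pd.Series(scores, index=measures.index, name="speech_factor")
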