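"""Group differences in developmental feature trajectories via linear
mixed-effects models.

For each feature the model is

    value ~ 1 + group * time + (1 | culture)

fitted by restricted maximum likelihood (REML), with the genotype group
effects-coded (+1/-1, so coefficients are symmetric around the grand mean)
and time in weeks centered at the first recording week. Fixed-effect t
tests use Satterthwaite approximate denominator degrees of freedom, computed
from the curvature of the restricted log-likelihood with respect to the two
variance components (random-intercept and residual variance). P values are
Bonferroni-adjusted across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "LMMResult",
    "fit_lmm_trajectory",
    "fit_lmm_table",
    "adjust_bonferroni",
    "significance_stars",
]

COEF_NAMES = ("intercept", "group", "time", "group_x_time")


@dataclass
class LMMResult:
    """Fixed-effect estimates and tests for one feature's trajectory model."""

    feature: str
    coef: Dict[str, float]
    se: Dict[str, float]
    df: Dict[str, float]
    p: Dict[str, float]
    sigma2_subject: float
    sigma2_resid: float
    singular: bool
    n_obs: int
    n_subjects: int

    def row(self) -> dict:
        out = {"feature": self.feature}
        for c in COEF_NAMES:
            out[f"beta_{c}"] = self.coef[c]
            out[f"se_{c}"] = self.se[c]
            out[f"df_{c}"] = self.df[c]
            out[f"p_{c}"] = self.p[c]
        out.update(
            sigma2_subject=self.sigma2_subject,
            sigma2_resid=self.sigma2_resid,
            singular=self.singular,
            n_obs=self.n_obs,
            n_subjects=self.n_subjects,
        )
        return out


def _reml_loglik(
    theta: np.ndarray, y: np.ndarray, X: np.ndarray, subj_codes: np.ndarray
) -> float:
    """Restricted log-likelihood of the random-intercept model at
    theta = (sigma2_subject, sigma2_resid), profiling out the fixed effects.

    Uses the closed form for block-diagonal Sigma_j = s2e I + s2b J via the
    Woodbury identity, so each evaluation is O(n).
    """
    s2b, s2e = float(theta[0]), float(theta[1])
    if s2e <= 0 or s2b < 0:
        return -np.inf
    n, p = X.shape
    logdet = 0.0
    XtSiX = np.zeros((p, p))
    XtSiy = np.zeros(p)
    ytSiy = 0.0
    for code in np.unique(subj_codes):
        m = subj_codes == code
        nj = int(m.sum())
        Xj, yj = X[m], y[m]
        c = s2b / (s2e + nj * s2b)
        logdet += (nj - 1) * np.log(s2e) + np.log(s2e + nj * s2b)
        xs, ys = Xj.sum(axis=0), yj.sum()
        XtSiX += (Xj.T @ Xj - c * np.outer(xs, xs)) / s2e
        XtSiy += (Xj.T @ yj - c * xs * ys) / s2e
        ytSiy += (yj @ yj - c * ys * ys) / s2e
    beta = np.linalg.solve(XtSiX, XtSiy)
    quad = ytSiy - beta @ XtSiy
    sign, logdet_x = np.linalg.slogdet(XtSiX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdet + logdet_x + quad + (n - p) * np.log(2 * np.pi))


def _beta_cov(
    theta: np.ndarray, X: np.ndarray, subj_codes: np.ndarray
) -> np.ndarray:
    """GLS covariance of the fixed effects, (X' Sigma^-1 X)^-1."""
    s2b, s2e = float(theta[0]), float(theta[1])
    p = X.shape[1]
    XtSiX = np.zeros((p, p))
    for code in np.unique(subj_codes):
        m = subj_codes == code
        nj = int(m.sum())
        Xj = X[m]
        c = s2b / (s2e + nj * s2b)
        xs = Xj.sum(axis=0)
        XtSiX += (Xj.T @ Xj - c * np.outer(xs, xs)) / s2e
    return np.linalg.inv(XtSiX)


def _satterthwaite_df(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    subj_codes: np.ndarray,
) -> np.ndarray:
    """Per-coefficient Satterthwaite denominator degrees of freedom.

    df_i = 2 g_i^2 / (grad_i' A grad_i) with g_i(theta) = Var(beta_i),
    gradients by central differences and A the inverse observed information
    of the restricted log-likelihood over theta.
    """
    n, p = X.shape
    h = np.maximum(np.abs(theta), 1e-6) * 1e-4

    def ll(t):
        return _reml_loglik(t, y, X, subj_codes)

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ti = np.array(theta, dtype=float)
            f = np.zeros(4)
            steps = [(+1, +1), (+1, -1), (-1, +1), (-1, -1)]
            for k, (si, sj) in enumerate(steps):
                t = ti.copy()
                t[i] += si * h[i]
                t[j] += sj * h[j]
                t[0] = max(t[0], 0.0)
                f[k] = ll(t)
            H[i, j] = (f[0] - f[1] - f[2] + f[3]) / (4 * h[i] * h[j])
    info = -H
    try:
        A = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(info)

    dfs = np.empty(p)
    for i in range(p):
        grad = np.zeros(2)
        for j in range(2):
            tp = np.array(theta, dtype=float)
            tm = np.array(theta, dtype=float)
            tp[j] += h[j]
            tm[j] = max(tm[j] - h[j], 0.0)
            gp = _beta_cov(tp, X, subj_codes)[i, i]
            gm = _beta_cov(tm, X, subj_codes)[i, i]
            grad[j] = (gp - gm) / (tp[j] - tm[j])
        denom = grad @ A @ grad
        g = _beta_cov(theta, X, subj_codes)[i, i]
        if denom <= 0 or not np.isfinite(denom):
            dfs[i] = n - p
        else:
            dfs[i] = np.clip(2 * g * g / denom, 1.0, n - p)
    return dfs


def fit_lmm_trajectory(
    table: pd.DataFrame,
    feature: Optional[str] = None,
    time_col: str = "age_week",
    value_col: str = "value",
    subject_col: str = "culture_id",
    group_col: str = "group",
) -> LMMResult:
    """Fit value ~ 1 + group*time + (1 | subject) by REML for one feature.

    ``table`` is long-format; when ``feature`` is given rows are filtered on
    the ``feature`` column. Group is effects-coded (+1 for the first sorted
    level, -1 for the second); time is centered at the first observed week.
    A singular (zero) random-intercept variance keeps the fit and sets the
    ``singular`` flag.
    """
    t = table.copy()
    if feature is not None and "feature" in t.columns:
        t = t[t["feature"] == feature]
    t = t.dropna(subset=[value_col])
    levels = np.sort(t[group_col].unique())
    if levels.size != 2:
        raise ValueError("the trajectory model expects exactly 2 groups")
    g = np.where(t[group_col].to_numpy() == levels[0], 1.0, -1.0)
    time = t[time_col].to_numpy(float)
    time_c = time - time.min()
    y = t[value_col].to_numpy(float)
    X = np.column_stack([np.ones_like(y), g, time_c, g * time_c])
    subj = pd.factorize(t[subject_col])[0]

    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # optimizers can hit singular information at the sigma2_b = 0
        # boundary; fall through a short cascade before giving up
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = MixedLM(y, X, groups=subj).fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if res is None:
        raise np.linalg.LinAlgError("mixed-model fit failed to converge")
    beta = np.asarray(res.fe_params)
    s2e = float(res.scale)
    s2b = float(np.asarray(res.cov_re)[0, 0])
    singular = s2b < 1e-8 * (s2b + s2e)
    theta = np.array([max(s2b, 0.0), s2e])

    V = _beta_cov(theta, X, subj)
    se = np.sqrt(np.diag(V))
    dfs = _satterthwaite_df(theta, y, X, subj)
    tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), dfs)

    return LMMResult(
        feature=feature if feature is not None else value_col,
        coef=dict(zip(COEF_NAMES, beta)),
        se=dict(zip(COEF_NAMES, se)),
        df=dict(zip(COEF_NAMES, dfs)),
        p=dict(zip(COEF_NAMES, pvals)),
        sigma2_subject=s2b,
        sigma2_resid=s2e,
        singular=singular,
        n_obs=len(y),
        n_subjects=int(np.unique(subj).size),
    )


def adjust_bonferroni(p_values, n_features: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * n)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p) if n_features is None else int(n_features)
    return np.minimum(p * n, 1.0)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fit_lmm_table(
    feature_table: pd.DataFrame,
    features: Optional[list] = None,
    time_col: str = "age_week",
) -> pd.DataFrame:
    """Fit the trajectory model per feature and Bonferroni-adjust p values.

    Returns one row per feature with coefficients, Satterthwaite tests,
    adjusted p values and significance stars for the group and
    group-by-time effects.
    """
    if features is None:
        features = sorted(feature_table["feature"].unique())
    rows = []
    for feat in features:
        try:
            rows.append(fit_lmm_trajectory(feature_table, feat, time_col).row())
        except (ValueError, np.linalg.LinAlgError) as err:
            rows.append({"feature": feat, "error": str(err)})
    out = pd.DataFrame(rows)
    n = len(features)
    for c in ("group", "group_x_time"):
        if f"p_{c}" in out.columns:
            out[f"p_adj_{c}"] = adjust_bonferroni(out[f"p_{c}"], n)
            out[f"stars_{c}"] = [
                significance_stars(p) if np.isfinite(p) else ""
                for p in out[f"p_adj_{c}"]
            ]
    return out
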