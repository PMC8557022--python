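"""Row-wise ordinary least squares and empirical-Bayes variance moderation.

Shared fitting machinery for the methylation (M-value) and expression
(log-CPM) linear models.  Each feature (probe or gene) is a row of the
response matrix; the design matrix is common to all rows, so the fit is a
single matrix product rather than a per-row loop.

The moderation step shrinks per-feature residual variances toward a pooled
prior fitted by method of moments on the log-variance scale (a scaled
inverse-chi-square prior, the classic microarray approach): the prior
degrees of freedom ``d0`` come from inverting the trigamma relation for the
spread of log-variances and the prior variance ``s0^2`` from their mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import digamma, polygamma

from .errors import InvalidDesignError


@dataclass
class RowOlsResult:
    """Per-row OLS results for one contrast coefficient."""

    effect: np.ndarray       # coefficient of interest, per row
    se: np.ndarray           # its (unmoderated) standard error
    sigma2: np.ndarray       # residual variance per row
    df_resid: int            # residual degrees of freedom (shared)
    t: np.ndarray            # effect / se
    p: np.ndarray            # two-sided p from t distribution


def rowwise_ols(y: np.ndarray, design: np.ndarray, coef_index: int) -> RowOlsResult:
    """Fit ``y[i, :] ~ design`` for every row ``i`` and test one coefficient.

    Parameters
    ----------
    y : (n_features, n_samples) response matrix.
    design : (n_samples, n_params) design matrix; must be full column rank.
    coef_index : column of `design` whose coefficient is reported.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(design, dtype=float)
    n, p = x.shape
    if y.shape[1] != n:
        raise InvalidDesignError(
            f"response has {y.shape[1]} samples but design has {n} rows"
        )
    if np.linalg.matrix_rank(x) < p:
        raise InvalidDesignError("design matrix is rank deficient")
    df = n - p
    if df < 1:
        raise InvalidDesignError("no residual degrees of freedom")

    xtx_inv = np.linalg.inv(x.T @ x)
    # beta-hat for all rows at once: (features x params)
    coefs = y @ x @ xtx_inv
    resid = y - coefs @ x.T
    sigma2 = np.einsum("ij,ij->i", resid, resid) / df
    v = xtx_inv[coef_index, coef_index]
    effect = coefs[:, coef_index]
    se = np.sqrt(np.maximum(sigma2 * v, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return RowOlsResult(effect=effect, se=se, sigma2=sigma2, df_resid=df, t=t, p=pvals)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-12 * abs(x):
            break
    return float(x)


def fit_variance_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Returns ``(d0, s0_sq)``; ``d0`` may be ``inf`` when the observed
    log-variances are no more dispersed than pure chi-square sampling noise.
    """
    s2 = np.asarray(sigma2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(np.mean(sigma2)) if len(sigma2) else 1.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderate(res: RowOlsResult) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Empirical-Bayes moderation of a row-wise OLS fit.

    Returns ``(t_mod, p_mod, df_total, d0, s0_sq)`` where ``df_total =
    df_resid + d0`` (capped for the infinite-prior case).
    """
    d0, s0_sq = fit_variance_prior(res.sigma2, res.df_resid)
    df = res.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(res.sigma2, s0_sq)
        df_total = 1e6
    else:
        s2_post = (d0 * s0_sq + df * res.sigma2) / (d0 + df)
        df_total = df + d0
    # se scales with posterior sd; the design factor cancels in the ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.sqrt(np.where(res.sigma2 > 0, s2_post / res.sigma2, 1.0))
        se_mod = np.where(
            res.sigma2 > 0, res.se * scale, np.sqrt(s2_post) * _safe_v(res)
        )
        t_mod = np.where(se_mod > 0, res.effect / np.where(se_mod > 0, se_mod, 1.0), 0.0)
    p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    return t_mod, p_mod, float(df_total), float(d0), float(s0_sq)


def _safe_v(res: RowOlsResult) -> float:
    """Design-variance factor recovered from any row with positive variance."""
    pos = res.sigma2 > 0
    if not np.any(pos):
        return 1.0
    i = int(np.argmax(pos))
    return float(res.se[i] / np.sqrt(res.sigma2[i]))
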