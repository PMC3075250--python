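"""Model performance: discrimination, calibration, overfitting, comparisons.

Patient-level indices reported for each fitted cohort: ROC area
(concordance, ties at 1/2), likelihood-ratio generalized R^2 (with the
max-rescaled variant available), overfitting intercept/slope from the
recalibration regression of outcomes on the frozen derivation risk score,
a decile calibration table, and a Pearson-residual summary. Group-level
agreement between two sets of standardized rates (e.g. claims-based vs
chart-based state rates) is summarized by a weighted regression line, a
weighted correlation with a Fisher-z large-sample standard error, and the
distribution of paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .hglm import GLMFit, HGLMFit, fit_logistic

__all__ = [
    "roc_auc",
    "generalized_r2",
    "overfitting_indices",
    "decile_table",
    "pearson_residual_summary",
    "compare_rsmr_sets",
    "RSMRComparison",
    "performance_report",
]


def roc_auc(predicted, outcomes) -> float:
    """Area under the ROC curve = P(score_case > score_control) + ties/2."""
    y = np.asarray(outcomes, dtype=int)
    p = np.asarray(predicted, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC area undefined: only one outcome class present")
    return float(roc_auc_score(y, p))


def generalized_r2(
    loglik_model: float, loglik_null: float, n: int, *, max_rescaled: bool = False
) -> float:
    """Likelihood-ratio generalized R^2.

    R^2 = 1 - exp(-2 (l_model - l_null) / n). With ``max_rescaled`` the
    value is divided by its attainable maximum 1 - exp(2 l_null / n)
    (relevant for binary outcomes, where plain R^2 cannot reach 1).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_model < loglik_null - 1e-9:
        raise ValueError("model log-likelihood below null log-likelihood")
    r2 = 1.0 - np.exp(-2.0 * (loglik_model - loglik_null) / n)
    if max_rescaled:
        r2 /= 1.0 - np.exp(2.0 * loglik_null / n)
    return float(r2)


def overfitting_indices(
    fit: GLMFit | HGLMFit, X_val, y_val
) -> tuple[float, float]:
    """Recalibration (overfitting) intercept and slope.

    The risk score is the frozen fixed-effects linear predictor
    mu + x'beta from the derivation fit; outcomes in the target cohort are
    regressed on that single score by logistic regression. (0, 1) means
    the derivation model transports without overfitting; slope < 1 signals
    attenuation.
    """
    score = np.asarray(fit.linear_predictor(X_val), dtype=float)
    if np.std(score) < 1e-12:
        raise ValueError("degenerate (constant) risk score")
    refit = fit_logistic(score[:, None], y_val)
    return float(refit.params.iloc[0]), float(refit.params.iloc[1])


def decile_table(predicted, outcomes) -> tuple[pd.DataFrame, float]:
    """Observed mortality within predicted-probability deciles.

    Rank-based assignment with ties going to the lower decile and
    near-equal bin sizes. Returns the 10-row table and the observed-rate
    range (highest decile minus lowest decile).
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n = len(p)
    if n < 10:
        raise ValueError("need at least 10 observations for deciles")
    order = np.argsort(p, kind="mergesort")  # stable: ties keep input order
    decile = np.empty(n, dtype=int)
    decile[order] = (np.arange(n) * 10) // n
    rows = []
    for d in range(10):
        sel = decile == d
        rows.append(
            {
                "decile": d + 1,
                "n": int(sel.sum()),
                "p_low": float(p[sel].min()) if sel.any() else np.nan,
                "p_high": float(p[sel].max()) if sel.any() else np.nan,
                "mean_predicted": float(p[sel].mean()) if sel.any() else np.nan,
                "observed_rate": float(y[sel].mean()) if sel.any() else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    obs_range = float(table["observed_rate"].iloc[9] - table["observed_rate"].iloc[0])
    return table, obs_range


def pearson_residual_summary(predicted, outcomes) -> dict:
    """Mean, SD and |r| > 3 count of Pearson residuals
    r_i = (y_i - p_i) / sqrt(p_i (1 - p_i)); fitted probabilities at 0 or 1
    are flagged rather than divided by."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    degenerate = (p <= 0) | (p >= 1)
    ok = ~degenerate
    r = (y[ok] - p[ok]) / np.sqrt(p[ok] * (1 - p[ok]))
    return {
        "mean": float(r.mean()),
        "sd": float(r.std(ddof=1)) if len(r) > 1 else np.nan,
        "n_beyond_3": int((np.abs(r) > 3).sum()),
        "n_flagged": int(degenerate.sum()),
    }


@dataclass
class RSMRComparison:
    """Weighted agreement summary between two aligned sets of rates."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    correlation: float
    correlation_se: float
    differences: pd.Series  # rate_a - rate_b per group

    def difference_summary(self) -> dict:
        d = self.differences
        return {
            "mean": float(d.mean()),
            "median": float(d.median()),
            "max": float(d.max()),
            "range": (float(d.min()), float(d.max())),
        }


def compare_rsmr_sets(pairs: pd.DataFrame, weights) -> RSMRComparison:
    """Weighted regression/correlation of ``rate_b`` on ``rate_a``.

    ``pairs`` needs columns ``rate_a`` and ``rate_b`` (one row per group,
    e.g. per state); ``weights`` are the group sizes (hospitalization
    counts). The correlation SE uses the Fisher-z large-sample
    approximation SE(r) ~= (1 - r^2) / sqrt(n - 3) with n the number of
    groups.
    """
    import statsmodels.api as sm

    if len(pairs) < 3:
        raise ValueError("need at least 3 groups")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    x = pairs["rate_a"].to_numpy(dtype=float)
    yv = pairs["rate_b"].to_numpy(dtype=float)
    res = sm.WLS(yv, sm.add_constant(x), weights=w).fit()
    wm = w / w.sum()
    mx, my = wm @ x, wm @ yv
    cov = wm @ ((x - mx) * (yv - my))
    vx, vy = wm @ (x - mx) ** 2, wm @ (yv - my) ** 2
    if vx == 0 or vy == 0:
        corr = np.nan
    else:
        corr = float(cov / np.sqrt(vx * vy))
    n = len(pairs)
    corr_se = (1 - corr**2) / np.sqrt(n - 3) if n > 3 and np.isfinite(corr) else np.nan
    return RSMRComparison(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        correlation=corr,
        correlation_se=float(corr_se),
        differences=pd.Series(x - yv, index=pairs.index),
    )


def performance_report(predicted, outcomes, loglik_model: float | None = None) -> dict:
    """Bundle the patient-level indices for one fitted cohort.

    When ``loglik_model`` is omitted it is computed from the predicted
    probabilities (Bernoulli log-likelihood), which equals the fit
    log-likelihood for a GLM scored on its own training data.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n = len(y)
    eps = 1e-12
    if loglik_model is None:
        loglik_model = float(
            (y * np.log(np.clip(p, eps, 1)) + (1 - y) * np.log(np.clip(1 - p, eps, 1))).sum()
        )
    ybar = y.mean()
    loglik_null = float(n * (ybar * np.log(ybar + eps) + (1 - ybar) * np.log(1 - ybar + eps)))
    table, obs_range = decile_table(p, y)
    return {
        "n": n,
        "observed_rate": float(ybar),
        "roc_auc": roc_auc(p, y),
        "generalized_r2": generalized_r2(loglik_model, loglik_null, n),
        "generalized_r2_max_rescaled": generalized_r2(
            loglik_model, loglik_null, n, max_rescaled=True
        ),
        "decile_table": table,
        "decile_range": obs_range,
        "pearson_residuals": pearson_residual_summary(p, y),
    }
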