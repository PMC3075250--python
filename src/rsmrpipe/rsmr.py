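"""Risk-standardized mortality rates by indirect standardization.

For hospital *h* with fitted random-intercept model (mu, beta, alpha_h):

    predicted deaths  P_h = sum_i expit(mu + x_i' beta + alpha_h)
    expected deaths   E_h = sum_i expit(mu + x_i' beta)
    RSMR_h            = (P_h / E_h) * national observed rate

The expected count uses the national intercept (random effect set to zero),
i.e. how many deaths the national model would produce for this hospital's
own case mix; the predicted count adds the hospital's empirical-Bayes
intercept. Hospitals whose effect is shrunk to zero land exactly at the
national rate. Interval estimates come from a cluster bootstrap that
resamples hospitals with replacement and refits the hierarchical model on
each resample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .hglm import HGLMConfig, HGLMFit, fit_random_intercept, posterior_modes

__all__ = [
    "predicted_deaths",
    "expected_deaths",
    "compute_rsmr",
    "rsmr_table",
    "bootstrap_intervals",
]


def _hospital_lp(fit: HGLMFit, rows) -> np.ndarray:
    return fit.linear_predictor(rows)


def predicted_deaths(fit: HGLMFit, rows, hospital_id) -> float:
    """P_h: model-predicted deaths for ``hospital_id`` given its own cases.

    Unknown hospital ids are an error — silently scoring with alpha = 0
    would conflate "average hospital" with "hospital we never fitted".
    """
    if hospital_id not in fit.alpha.index:
        raise KeyError(f"hospital {hospital_id!r} not present in fit")
    lp = _hospital_lp(fit, rows) + float(fit.alpha[hospital_id])
    return float(expit(lp).sum())


def expected_deaths(fit: HGLMFit, rows) -> float:
    """E_h: deaths expected under the national intercept for this case mix."""
    return float(expit(_hospital_lp(fit, rows)).sum())


def compute_rsmr(p_h: float, e_h: float, national_rate: float) -> float:
    """(P_h / E_h) x national observed rate; E_h must be positive."""
    if e_h <= 0:
        raise ValueError("expected deaths is 0: RSMR undefined for empty hospital")
    return (p_h / e_h) * national_rate


def rsmr_table(
    fit: HGLMFit,
    X,
    groups,
    outcomes,
    *,
    national_rate: float | None = None,
) -> pd.DataFrame:
    """Per-hospital observed/predicted/expected deaths and RSMR.

    ``national_rate`` defaults to the observed death rate over all rows
    passed in (the full-cohort unadjusted rate).
    """
    X = pd.DataFrame(X)
    groups = np.asarray(groups)
    y = np.asarray(outcomes, dtype=float)
    if national_rate is None:
        national_rate = float(y.mean())
    rows = []
    for h in pd.unique(groups):
        sel = groups == h
        sub = X.loc[sel]
        p_h = predicted_deaths(fit, sub, h)
        e_h = expected_deaths(fit, sub)
        rows.append(
            {
                "hospital_id": h,
                "n": int(sel.sum()),
                "observed_deaths": int(y[sel].sum()),
                "predicted_deaths": p_h,
                "expected_deaths": e_h,
                "rsmr": compute_rsmr(p_h, e_h, national_rate),
            }
        )
    out = pd.DataFrame(rows).sort_values("hospital_id").reset_index(drop=True)
    out.attrs["national_rate"] = national_rate
    return out


def bootstrap_intervals(
    X,
    y,
    groups,
    *,
    B: int = 200,
    seed: int = 0,
    level: float = 0.95,
    hglm_config: HGLMConfig | None = None,
) -> pd.DataFrame:
    """Percentile cluster-bootstrap intervals for per-hospital RSMRs.

    Hospitals are resampled with replacement; the hierarchical model is
    refit on each resample; a hospital's replicate RSMR uses its own cases
    scored with the replicate's (mu, beta, tau) — its replicate hospital
    intercept is the posterior mode of its own cases under those
    parameters — and the replicate cohort's observed national rate. The
    interval for a hospital is taken over the replicates in which it
    appears; a hospital absent from every replicate gets NaN bounds.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    hospitals = np.array(sorted(pd.unique(groups)))
    idx_by_h = {h: np.where(groups == h)[0] for h in hospitals}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))

    replicates: dict[object, list[float]] = {h: [] for h in hospitals}
    for _ in range(B):
        draw = rng.choice(hospitals, size=len(hospitals), replace=True)
        parts = []
        glabels = []
        for copy_i, h in enumerate(draw):
            parts.append(idx_by_h[h])
            glabels.append(np.full(len(idx_by_h[h]), copy_i))
        rows = np.concatenate(parts)
        gb = np.concatenate(glabels)
        fit_b = fit_random_intercept(X.iloc[rows], y[rows], gb, hglm_config)
        rate_b = float(y[rows].mean())
        for h in pd.unique(draw):
            sel = idx_by_h[h]
            sub = X.iloc[sel]
            alpha_h = float(
                posterior_modes(
                    sub, y[sel], np.zeros(len(sel)), fit_b.mu, fit_b.beta, fit_b.tau
                ).iloc[0]
            )
            lp = fit_b.linear_predictor(sub)
            p_h = float(expit(lp + alpha_h).sum())
            e_h = float(expit(lp).sum())
            replicates[h].append(compute_rsmr(p_h, e_h, rate_b))

    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows_out = []
    for h in hospitals:
        vals = np.asarray(replicates[h])
        if len(vals) == 0:
            rows_out.append((h, np.nan, np.nan, level, 0))
        else:
            rows_out.append(
                (h, float(np.quantile(vals, lo_q)), float(np.quantile(vals, hi_q)),
                 level, len(vals))
            )
    return pd.DataFrame(
        rows_out, columns=["hospital_id", "lower", "upper", "level", "n_replicates"]
    )
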