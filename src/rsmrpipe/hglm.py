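"""Random-intercept hierarchical logistic regression for hospital profiling.

Model: for patient *i* in hospital *h*,

    y_ih ~ Bernoulli(p_ih),  logit p_ih = mu + x_ih' beta + alpha_h,
    alpha_h ~ Normal(0, tau^2),

with mu the national intercept, beta the patient-level (case-mix) effects
and alpha_h a latent hospital effect. Estimation maximizes the marginal
likelihood, integrating alpha_h out by adaptive Gauss–Hermite quadrature
(the integrand is re-centered and re-scaled at each hospital's posterior
mode; one quadrature point recovers the Laplace approximation). Hospital
effects are reported as empirical-Bayes posterior modes with Laplace
posterior standard deviations — shrunk toward zero in proportion to how
little data the hospital contributes.

Variable selection is performed separately, by backward elimination under
an ordinary logistic GLM with a Wald-p exit criterion, after which the
retained covariates are re-estimated under the hierarchical model.

An independent fixed high-order quadrature evaluator
(:func:`marginal_loglik_oracle`) is provided for verification; it shares no
code path with the adaptive fitter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = [
    "GLMFit",
    "HGLMFit",
    "HGLMConfig",
    "fit_logistic",
    "backward_eliminate",
    "fit_random_intercept",
    "marginal_loglik_oracle",
    "posterior_modes",
    "SeparationError",
]

INTERCEPT = "(mu)"


class SeparationError(RuntimeError):
    """Raised when the likelihood is degenerate (complete separation)."""


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


@dataclass
class GLMFit:
    """Ordinary logistic regression fit (maximum likelihood)."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    n: int
    converged: bool

    @property
    def mu(self) -> float:
        return float(self.params[INTERCEPT])

    @property
    def beta(self) -> pd.Series:
        return self.params.drop(INTERCEPT)

    def linear_predictor(self, X) -> np.ndarray:
        M, cols = _as_matrix(X)
        b = self.beta
        if list(b.index) != cols:
            b = b.reindex(cols)
            if b.isna().any():
                raise KeyError(f"design columns {cols} do not match fit {list(self.beta.index)}")
        return self.mu + M @ b.to_numpy()


def screen_separation(X: pd.DataFrame, y) -> list[str]:
    """Binary columns that quasi-separate the outcome (an empty cell in the
    2x2 table with y), which would send the MLE to infinity."""
    y = np.asarray(y, dtype=int)
    bad = []
    for c in X.columns:
        col = X[c].to_numpy()
        vals = np.unique(col)
        if len(vals) <= 1:
            bad.append(str(c))
            continue
        if set(vals) <= {0, 1}:
            on = col == 1
            if y[on].min() == y[on].max() or y[~on].min() == y[~on].max():
                bad.append(str(c))
    return bad


def fit_logistic(X, y, *, maxiter: int = 200, tol: float = 1e-10) -> GLMFit:
    """Maximum-likelihood logistic regression of ``y`` on ``X`` + intercept.

    Raises :class:`SeparationError`, naming the offending columns, when the
    data are completely separated (diverging coefficients), and
    ``RuntimeError`` on non-convergence.
    """
    M, cols = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    design = np.hstack([np.ones((len(M), 1)), M])
    names = [INTERCEPT] + cols
    model = sm.Logit(y, design)
    try:
        res = model.fit(disp=0, maxiter=maxiter, tol=tol, method="newton")
    except Exception as err:  # statsmodels raises on perfect separation
        raise SeparationError(f"logistic fit failed: {err}") from err
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 30):
        bad = [names[j] for j in np.where(np.abs(params) > 30)[0]]
        raise SeparationError(f"separation-degenerate columns: {bad}")
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")
    return GLMFit(
        params=pd.Series(params, index=names),
        bse=pd.Series(np.asarray(res.bse, dtype=float), index=names),
        pvalues=pd.Series(np.asarray(res.pvalues, dtype=float), index=names),
        loglik=float(res.llf),
        n=len(y),
        converged=True,
    )


def backward_eliminate(
    X: pd.DataFrame,
    y,
    alpha_exit: float = 0.01,
    *,
    forced: Sequence[str] = (),
) -> tuple[list[str], GLMFit, pd.DataFrame]:
    """Backward elimination under the logistic GLM.

    Repeatedly removes the single covariate with the largest Wald p-value
    exceeding ``alpha_exit`` (ties: largest p, then smallest |z|, then
    later column position) and refits, until every remaining covariate has
    p <= alpha_exit. Columns in ``forced`` (e.g. demographics) are never
    candidates for removal. Returns the retained columns, the final fit
    and the removal trace.
    """
    if not 0 < alpha_exit <= 1:
        raise ValueError("alpha_exit must be in (0, 1]")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in X.columns]
    cols = [str(c) for c in X.columns]
    unknown = set(forced) - set(cols)
    if unknown:
        raise KeyError(f"forced columns not in design: {sorted(unknown)}")
    trace = []
    while True:
        fit = fit_logistic(X[cols], y)
        removable = [c for c in cols if c not in forced]
        if not removable:
            break
        p = fit.pvalues[removable]
        z = (fit.params[removable] / fit.bse[removable]).abs()
        order = sorted(
            removable, key=lambda c: (-p[c], z[c], cols.index(c))
        )
        worst = order[0]
        if alpha_exit >= 1 or p[worst] <= alpha_exit:
            break
        trace.append((worst, float(p[worst])))
        cols = [c for c in cols if c != worst]
    return cols, fit, pd.DataFrame(trace, columns=["removed", "p_value"])


@dataclass(frozen=True)
class HGLMConfig:
    """Estimation controls for the adaptive-quadrature fitter."""

    n_quad: int = 15
    max_iter: int = 200
    ftol: float = 1e-12
    gtol: float = 1e-7
    mode_tol: float = 1e-11
    tau_max: float = 20.0
    tau_boundary: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_quad < 1:
            raise ValueError("n_quad must be >= 1")


@dataclass
class HGLMFit:
    """Fitted random-intercept logistic model.

    ``alpha`` holds the empirical-Bayes (posterior-mode) hospital
    intercepts on the log-odds scale, in a mean-zero parameterization with
    the national intercept ``mu`` kept separate; ``alpha_sd`` their Laplace
    posterior standard deviations. ``se`` covers ``(mu)``, each covariate
    and ``(tau)`` (NaN when tau sits at the zero boundary).
    """

    mu: float
    beta: pd.Series
    tau: float
    alpha: pd.Series
    alpha_sd: pd.Series
    se: pd.Series
    loglik: float
    n: int
    n_groups: int
    converged: bool
    n_iter: int
    tau_at_boundary: bool
    config: HGLMConfig = field(default_factory=HGLMConfig)

    def linear_predictor(self, X) -> np.ndarray:
        """Fixed-effects linear predictor mu + X beta (no hospital effect)."""
        M, cols = _as_matrix(X)
        b = self.beta.reindex(cols)
        if b.isna().any():
            raise KeyError(
                f"design columns {cols} do not match fit {list(self.beta.index)}"
            )
        return self.mu + M @ b.to_numpy()

    def to_json(self, path=None) -> str:
        payload = {
            "mu": self.mu,
            "beta": {str(k): float(v) for k, v in self.beta.items()},
            "tau": self.tau,
            "alpha": {str(k): float(v) for k, v in self.alpha.items()},
            "alpha_sd": {str(k): float(v) for k, v in self.alpha_sd.items()},
            "se": {str(k): (None if np.isnan(v) else float(v)) for k, v in self.se.items()},
            "loglik": self.loglik,
            "n": self.n,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "tau_at_boundary": self.tau_at_boundary,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "HGLMFit":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        se = pd.Series(payload["se"], dtype=float)
        return cls(
            mu=payload["mu"],
            beta=pd.Series(payload["beta"], dtype=float),
            tau=payload["tau"],
            alpha=pd.Series(payload["alpha"], dtype=float),
            alpha_sd=pd.Series(payload["alpha_sd"], dtype=float),
            se=se,
            loglik=payload["loglik"],
            n=payload["n"],
            n_groups=payload["n_groups"],
            converged=payload["converged"],
            n_iter=payload["n_iter"],
            tau_at_boundary=payload["tau_at_boundary"],
        )


def _group_index(groups) -> tuple[np.ndarray, np.ndarray]:
    codes, labels = pd.factorize(np.asarray(groups), sort=True)
    return codes, np.asarray(labels)


def _bernoulli_ll(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + exp(eta)), stable via logaddexp
    return y * eta - np.logaddexp(0.0, eta)


class _AGQ:
    """Adaptive Gauss–Hermite machinery over a fixed (X, y, groups) block."""

    def __init__(self, M: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int, n_quad: int, mode_tol: float):
        order = np.argsort(codes, kind="stable")
        self.M = M[order]
        self.y = y[order]
        self.codes = codes[order]
        self.H = n_groups
        counts = np.bincount(self.codes, minlength=n_groups)
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.nodes, self.weights = np.polynomial.hermite.hermgauss(n_quad)
        self.log_w = np.log(self.weights)
        self.mode_tol = mode_tol
        self._modes = np.zeros(n_groups)

    def _sums(self, eta_fix: np.ndarray, alpha_per_group: np.ndarray):
        """Per-group sum of (y - p) and p(1-p) at alpha_per_group."""
        eta = eta_fix + alpha_per_group[self.codes]
        p = expit(eta)
        s1 = np.add.reduceat(self.y - p, self.starts)
        s2 = np.add.reduceat(p * (1 - p), self.starts)
        return s1, s2

    def find_modes(self, eta_fix: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
        inv_t2 = 1.0 / (tau * tau)
        m = self._modes.copy()
        for _ in range(100):
            s1, s2 = self._sums(eta_fix, m)
            grad = s1 - m * inv_t2
            curv = s2 + inv_t2
            step = grad / curv
            np.clip(step, -4.0, 4.0, out=step)
            m = m + step
            if np.max(np.abs(grad)) < self.mode_tol:
                break
        self._modes = m
        _, s2 = self._sums(eta_fix, m)
        return m, s2 + inv_t2

    def loglik(self, eta_fix: np.ndarray, tau: float) -> float:
        if tau <= 0:
            return float(_bernoulli_ll(eta_fix, self.y).sum())
        m, curv = self.find_modes(eta_fix, tau)
        s = 1.0 / np.sqrt(curv)  # (H,)
        # alpha grid: H x K
        alpha = m[:, None] + np.sqrt(2.0) * s[:, None] * self.nodes[None, :]
        eta = eta_fix[:, None] + alpha[self.codes]
        ll = _bernoulli_ll(eta, self.y[:, None])  # n x K
        per_group = np.add.reduceat(ll, self.starts, axis=0)  # H x K
        log_prior = (
            -0.5 * (alpha / tau) ** 2 - np.log(tau) - 0.5 * np.log(2 * np.pi)
        )
        g = per_group + log_prior + self.nodes[None, :] ** 2 + self.log_w[None, :]
        lh = logsumexp(g, axis=1) + np.log(np.sqrt(2.0) * s)
        return float(lh.sum())


def fit_random_intercept(
    X,
    y,
    groups,
    config: HGLMConfig | None = None,
    *,
    start: Sequence[float] | None = None,
) -> HGLMFit:
    """Fit the random-intercept logistic model by adaptive quadrature.

    Parameters are (mu, beta, tau) with tau constrained to [0, tau_max];
    an estimate at the zero boundary is flagged (``tau_at_boundary``), not
    an error, and the model then coincides with the ordinary GLM. Standard
    errors come from the numerically differentiated observed information
    of the marginal log-likelihood.
    """
    cfg = config or HGLMConfig()
    M, cols = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    codes, labels = _group_index(groups)
    H = len(labels)
    if H < 2:
        raise ValueError("need at least 2 hospitals to identify tau")
    agq = _AGQ(M, y, codes, H, cfg.n_quad, cfg.mode_tol)

    if start is None:
        glm = fit_logistic(M, y)
        x0 = np.concatenate([glm.params.to_numpy(), [0.25]])
    else:
        x0 = np.asarray(start, dtype=float)
        if len(x0) != M.shape[1] + 2:
            raise ValueError("start must be (mu, beta..., tau)")

    def nll(theta: np.ndarray) -> float:
        mu, b, tau = theta[0], theta[1:-1], theta[-1]
        eta_fix = mu + agq.M @ b
        return -agq.loglik(eta_fix, tau)

    bounds = [(None, None)] * (M.shape[1] + 1) + [(0.0, cfg.tau_max)]
    res = minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": cfg.max_iter, "ftol": cfg.ftol, "gtol": cfg.gtol},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        # line-search failure from finite-difference noise near the optimum;
        # polish with a derivative-free pass from the best point found
        def nll_clipped(theta):
            t = theta.copy()
            t[-1] = min(max(t[-1], 0.0), cfg.tau_max)
            return nll(t)

        start_nm = res.x.copy()
        start_nm[-1] = min(max(start_nm[-1], 0.0), cfg.tau_max)
        polish = minimize(
            nll_clipped,
            start_nm,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 5000},
        )
        if polish.fun <= res.fun + 1e-9:
            polish.x[-1] = min(max(polish.x[-1], 0.0), cfg.tau_max)
            res = polish
        else:
            raise RuntimeError(f"HGLM did not converge: {res.message}")
    theta = res.x
    mu, beta, tau = float(theta[0]), theta[1:-1], float(theta[-1])
    at_boundary = tau < cfg.tau_boundary

    eta_fix = mu + agq.M @ beta
    if tau == 0:
        alpha = np.zeros(H)
        alpha_sd = np.zeros(H)
    else:
        alpha, curv = agq.find_modes(eta_fix, tau)
        alpha_sd = 1.0 / np.sqrt(curv)

    se = _marginal_se(nll, theta, at_boundary)
    names = [INTERCEPT] + cols + ["(tau)"]

    return HGLMFit(
        mu=mu,
        beta=pd.Series(beta, index=cols),
        tau=tau,
        alpha=pd.Series(alpha, index=labels),
        alpha_sd=pd.Series(alpha_sd, index=labels),
        se=pd.Series(se, index=names),
        loglik=float(-res.fun),
        n=len(y),
        n_groups=H,
        converged=bool(res.success),
        n_iter=int(res.nit),
        tau_at_boundary=at_boundary,
        config=cfg,
    )


def _marginal_se(nll, theta: np.ndarray, tau_at_boundary: bool) -> np.ndarray:
    """SEs from a central-difference Hessian of the negative log-likelihood."""
    k = len(theta)
    free = list(range(k - 1)) if tau_at_boundary else list(range(k))
    h = 1e-4 * (1.0 + np.abs(theta))
    Hm = np.zeros((len(free), len(free)))
    f0 = nll(theta)
    for a, i in enumerate(free):
        for b, j in enumerate(free):
            if b < a:
                Hm[a, b] = Hm[b, a]
                continue
            ti, tj = np.zeros(k), np.zeros(k)
            ti[i] = h[i]
            tj[j] = h[j]
            if i == j:
                f_pp = nll(theta + 2 * ti)
                f_mm = nll(theta - 2 * ti)
                Hm[a, a] = (f_pp - 2 * f0 + f_mm) / (4 * h[i] ** 2)
            else:
                f_pp = nll(theta + ti + tj)
                f_pm = nll(theta + ti - tj)
                f_mp = nll(theta - ti + tj)
                f_mm = nll(theta - ti - tj)
                Hm[a, b] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
    se = np.full(k, np.nan)
    try:
        cov = np.linalg.inv(Hm)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        se[free] = np.sqrt(d)
    except np.linalg.LinAlgError:
        pass
    return se


def posterior_modes(X, y, groups, mu: float, beta, tau: float) -> pd.Series:
    """Empirical-Bayes hospital intercepts at fixed (mu, beta, tau).

    Used when scoring hospitals under parameters estimated elsewhere
    (e.g. bootstrap replicates). tau = 0 pins every effect at zero.
    """
    M, cols = _as_matrix(X)
    if isinstance(beta, pd.Series):
        beta = beta.reindex(cols).to_numpy()
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, labels = _group_index(groups)
    if tau <= 0:
        return pd.Series(np.zeros(len(labels)), index=labels)
    agq = _AGQ(M, y, codes, len(labels), 1, 1e-11)
    eta_fix = mu + agq.M @ beta
    m, _ = agq.find_modes(eta_fix, tau)
    return pd.Series(m, index=labels)


def marginal_loglik_oracle(
    X, y, groups, mu: float, beta, tau: float, *, n_points: int = 201
) -> float:
    """Independent fixed-grid Gauss–Hermite evaluation of the marginal
    log-likelihood (no optimization, no adaptive centering).

    Per hospital, integrates the Bernoulli likelihood against the
    Normal(0, tau^2) prior on a prior-centered ``n_points`` grid,
    accumulating in log space. Intended for verification on small
    instances; cost grows as n_points x n.
    """
    M, cols = _as_matrix(X)
    if isinstance(beta, pd.Series):
        beta = beta.reindex(cols).to_numpy()
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, labels = _group_index(groups)
    eta_fix = mu + M @ beta
    if tau <= 0:
        return float(_bernoulli_ll(eta_fix, y).sum())
    nodes, weights = np.polynomial.hermite.hermgauss(n_points)
    alpha_grid = np.sqrt(2.0) * tau * nodes  # (K,)
    total = 0.0
    for g in range(len(labels)):
        sel = codes == g
        eta = eta_fix[sel][:, None] + alpha_grid[None, :]
        ll = _bernoulli_ll(eta, y[sel][:, None]).sum(axis=0)  # (K,)
        total += logsumexp(ll + np.log(weights)) - 0.5 * np.log(np.pi)
    return float(total)
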