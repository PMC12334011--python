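"""Transition-probability estimation by random-intercept logistic regression.

Each of the 11 modeled arrows gets its own binary regression on the
origin state's risk set, with a quadratic in (age - 16), sex and
race/ethnicity dummies (White men as reference), their interactions,
and a person-level Gaussian random intercept integrated out by
Gauss-Hermite quadrature (21 nodes by default).  With the intercept SD
fixed at zero the fit reduces exactly to ordinary logistic regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .model import PARAM_NAMES, STATES, TransitionParameters

__all__ = [
    "COEF_NAMES",
    "LogitFit",
    "design_matrix",
    "fit_random_intercept_logit",
    "fit_transition",
    "fit_all_transitions",
    "predict_probability",
    "subgroup_table",
    "params_from_subgroup_table",
    "simulate_logit_outcomes",
]

logger = logging.getLogger(__name__)

COEF_NAMES = (
    "const",
    "age_c",          # Age - 16
    "age_c_sq",       # (Age - 16)^2
    "woman",
    "black",
    "hispanic",
    "woman_x_black",
    "woman_x_hispanic",
)

_SEPARATION_THRESHOLD = 12.0


@dataclass
class LogitFit:
    """One transition outcome's random-intercept logistic fit."""

    outcome: str
    coef_names: tuple
    beta: np.ndarray
    sigma_u: float
    se_beta: np.ndarray
    se_sigma_u: float
    cov_beta: np.ndarray
    loglik: float
    n_obs: int
    n_persons: int
    n_nodes: int
    converged: bool
    warnings: list = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.beta[self.coef_names.index(name)])


def design_matrix(age, woman, black, hispanic) -> np.ndarray:
    """Design in :data:`COEF_NAMES` order from raw covariates (vectorized)."""
    age = np.asarray(age, dtype=float)
    woman = np.asarray(woman, dtype=float)
    black = np.asarray(black, dtype=float)
    hispanic = np.asarray(hispanic, dtype=float)
    age_c = age - 16.0
    return np.column_stack([
        np.ones_like(age_c), age_c, age_c ** 2, woman, black, hispanic,
        woman * black, woman * hispanic,
    ])


def _prepare_groups(groups):
    """Sort-order, reduceat boundaries, and per-obs group index."""
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    boundaries = np.concatenate(
        [[0], np.nonzero(sorted_groups[1:] != sorted_groups[:-1])[0] + 1]
    )
    group_idx = np.cumsum(np.concatenate(
        [[0], (sorted_groups[1:] != sorted_groups[:-1]).astype(int)]
    ))
    return order, boundaries, group_idx


def _plain_negloglik_and_grad(beta, y, X):
    eta = X @ beta
    p = expit(eta)
    eps = 1e-300
    nll = -float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return nll, -(X.T @ (y - p))


_SIGMA_FLOOR = 1e-6


def _posterior_modes(eta, y, sigma, boundaries, group_idx, n_groups):
    """Per-person mode and curvature of log f(y_i|u) + log phi(u; 0, sigma).

    The objective is strictly concave in u, so Newton from 0 converges.
    """
    m = np.zeros(n_groups)
    inv_var = 1.0 / sigma ** 2
    for _ in range(100):
        p = expit(eta + m[group_idx])
        g1 = np.add.reduceat(y - p, boundaries) - m * inv_var
        g2 = -np.add.reduceat(p * (1 - p), boundaries) - inv_var
        delta = g1 / g2
        m -= delta
        if np.abs(delta).max() < 1e-12:
            break
    return m, -g2  # mode, negative curvature (positive)


def _marginal_negloglik_and_grad(theta, y, X, boundaries, group_idx, nodes,
                                 log_weights, estimate_sigma):
    """Negative marginal log-likelihood and its gradient.

    ``theta`` is (beta, sigma_u) when ``estimate_sigma`` else just beta.
    The scalar random intercept is integrated out by adaptive
    Gauss-Hermite quadrature: nodes are centered at each person's
    posterior mode and scaled by the posterior curvature, which keeps
    the rule accurate for sigma_u well above 1.
    """
    if not estimate_sigma:
        return _plain_negloglik_and_grad(theta, y, X)
    beta, sigma = theta[:-1], max(theta[-1], _SIGMA_FLOOR)
    eta = X @ beta
    n_groups = boundaries.size
    mode, curv = _posterior_modes(eta, y, sigma, boundaries, group_idx, n_groups)
    scale = 1.0 / np.sqrt(curv)                              # (n_groups,)

    u_nodes = mode[:, None] + np.sqrt(2.0) * scale[:, None] * nodes[None, :]
    lin = eta[:, None] + u_nodes[group_idx]                  # (n_obs, K)
    p = expit(lin)
    eps = 1e-300
    ll_obs = y[:, None] * np.log(p + eps) + (1 - y[:, None]) * np.log(1 - p + eps)
    ll_person = np.add.reduceat(ll_obs, boundaries, axis=0)  # (n_groups, K)
    log_prior = (-0.5 * (u_nodes / sigma) ** 2
                 - 0.5 * np.log(2 * np.pi) - np.log(sigma))
    # adaptive rule: integral = sqrt(2)*s_i * sum_k w_k e^{z_k^2} g(u_ik)
    log_kernel = (log_weights + nodes ** 2)[None, :] + ll_person + log_prior
    ll_i = logsumexp(log_kernel, axis=1) + 0.5 * np.log(2.0) + np.log(scale)
    nll = -float(ll_i.sum())

    # gradient of the true marginal loglik approximated with the same rule:
    # E_posterior[score], with posterior node weights a_ik
    post = np.exp(log_kernel - logsumexp(log_kernel, axis=1, keepdims=True))
    post_obs = post[group_idx]                               # (n_obs, K)
    resid = (y[:, None] - p) * post_obs
    grad_beta = X.T @ resid.sum(axis=1)
    # d/dsigma log phi(u; sigma) = u^2/sigma^3 - 1/sigma
    grad_sigma = float(
        (post * (u_nodes ** 2 / sigma ** 3 - 1.0 / sigma)).sum())
    return nll, -np.concatenate([grad_beta, [grad_sigma]])


def _plain_logit_newton(y, X, maxiter: int = 25, tol: float = 1e-10) -> np.ndarray:
    """Ordinary logistic MLE by Newton-Raphson (warm start for the GH fit)."""
    beta = np.zeros(X.shape[1])
    pbar = y.mean()
    if 0 < pbar < 1:
        beta[0] = np.log(pbar / (1 - pbar))
    for _ in range(maxiter):
        p = expit(X @ beta)
        grad = X.T @ (y - p)
        w = np.clip(p * (1 - p), 1e-10, None)
        hess = X.T @ (w[:, None] * X)
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.abs(delta).max() < tol:
            break
    return beta


def _numeric_hessian(fun, theta, h=1e-5):
    k = theta.size
    hess = np.empty((k, k))
    for j in range(k):
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        hess[:, j] = (fun(tp)[1] - fun(tm)[1]) / (2 * h)
    return 0.5 * (hess + hess.T)


def fit_random_intercept_logit(y, X, groups, outcome: str = "",
                               coef_names: tuple | None = None,
                               n_nodes: int = 21,
                               fix_sigma_zero: bool = False) -> LogitFit:
    """Maximize the Gauss-Hermite marginal likelihood of a 0/1 outcome.

    ``groups`` identifies the person each observation belongs to.  If no
    person contributes more than one observation, the intercept SD is
    unidentified: the plain-logit solution is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y must be 1-D and aligned with the rows of X")
    if y.size == 0:
        raise ValueError("no observations")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if coef_names is None:
        coef_names = tuple(f"b{j}" for j in range(X.shape[1]))

    order, boundaries, group_idx = _prepare_groups(groups)
    y_s, X_s = y[order], X[order]
    n_groups = boundaries.size
    fit_warnings: list[str] = []

    if not fix_sigma_zero and n_groups == y.size:
        fit_warnings.append(
            "no within-person replication; sigma_u is unidentified and fixed to 0"
        )
        fix_sigma_zero = True

    z, w = hermgauss(n_nodes)
    log_weights = np.log(w)
    estimate_sigma = not fix_sigma_zero

    def objective(theta):
        return _marginal_negloglik_and_grad(
            theta, y_s, X_s, boundaries, group_idx, z, log_weights, estimate_sigma
        )

    beta0 = _plain_logit_newton(y_s, X_s)
    start = np.concatenate([beta0, [0.5]]) if estimate_sigma else beta0
    bounds = ([(None, None)] * X.shape[1] + [(0.0, None)]) if estimate_sigma else None
    res = minimize(objective, start, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10})
    if not res.success:
        raise RuntimeError(
            f"random-intercept logit for {outcome or 'outcome'} did not converge: "
            f"{res.message} (nit={res.nit}, |grad|={np.abs(res.jac).max():.3g})"
        )
    theta = res.x
    beta = theta[:X.shape[1]]
    sigma = float(theta[-1]) if estimate_sigma else 0.0

    if np.abs(beta).max() > _SEPARATION_THRESHOLD:
        fit_warnings.append(
            "possible quasi-separation: a coefficient exceeds "
            f"{_SEPARATION_THRESHOLD} in absolute value"
        )
        logger.warning("quasi-separation suspected for outcome %s", outcome)

    hess = _numeric_hessian(objective, theta)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((theta.size, theta.size), np.nan)
        se = np.full(theta.size, np.nan)
        fit_warnings.append("Hessian is singular; standard errors unavailable")

    k = X.shape[1]
    return LogitFit(
        outcome=outcome,
        coef_names=tuple(coef_names),
        beta=beta,
        sigma_u=sigma,
        se_beta=se[:k],
        se_sigma_u=float(se[-1]) if estimate_sigma else 0.0,
        cov_beta=cov[:k, :k],
        loglik=-res.fun,
        n_obs=y.size,
        n_persons=int(n_groups),
        n_nodes=n_nodes,
        converged=bool(res.success),
        warnings=fit_warnings,
    )


def _risk_set(transitions: pd.DataFrame, panel: pd.DataFrame, outcome: str):
    """(y, design, groups) for one arrow's origin-state risk set."""
    if outcome not in PARAM_NAMES:
        raise KeyError(f"unknown transition {outcome!r}")
    origin = outcome.split("->")[0]
    sub = transitions[transitions["from_state"] == origin]
    if sub.empty:
        raise ValueError(f"no observations with origin state {origin}")
    demo = panel.set_index(["person_id", "wave"])
    rows = demo.loc[list(zip(sub["person_id"], sub["from_wave"]))]
    X = design_matrix(
        rows["age"].to_numpy(),
        (rows["sex"].to_numpy() == "woman"),
        (rows["race"].to_numpy() == "Black"),
        (rows["race"].to_numpy() == "Hispanic"),
    )
    y = (sub["transition"] == outcome).to_numpy(dtype=float)
    return y, X, sub["person_id"].to_numpy()


def fit_transition(transitions: pd.DataFrame, panel: pd.DataFrame,
                   outcome: str, n_nodes: int = 21,
                   fix_sigma_zero: bool = False) -> LogitFit:
    """Fit one arrow's regression on its origin-state risk set."""
    y, X, groups = _risk_set(transitions, panel, outcome)
    return fit_random_intercept_logit(
        y, X, groups, outcome=outcome, coef_names=COEF_NAMES,
        n_nodes=n_nodes, fix_sigma_zero=fix_sigma_zero,
    )


def fit_all_transitions(transitions: pd.DataFrame, panel: pd.DataFrame,
                        n_nodes: int = 21,
                        fix_sigma_zero: bool = False) -> dict:
    """Fits for all 11 modeled arrows, keyed by arrow name."""
    return {
        name: fit_transition(transitions, panel, name, n_nodes=n_nodes,
                             fix_sigma_zero=fix_sigma_zero)
        for name in PARAM_NAMES
    }


def _integrated_prob(eta, sigma_u: float, n_nodes: int = 21):
    """Population-averaged P(y=1): E_u[expit(eta + u)], u ~ N(0, sigma^2)."""
    eta = np.asarray(eta, dtype=float)
    if sigma_u == 0:
        return expit(eta)
    z, w = hermgauss(n_nodes)
    probs = expit(eta[..., None] + np.sqrt(2.0) * sigma_u * z)
    return probs @ (w / np.sqrt(np.pi))


def predict_probability(fit: LogitFit, age: float, sex: str, race: str,
                        integrate_random_effect: bool = True) -> float:
    """Predicted transition probability for one covariate cell.

    With integration off the prediction is at u = 0 (the median person);
    with integration on the random intercept is integrated out by
    quadrature (population-averaged).
    """
    x = design_matrix([age], [sex == "woman"], [race == "Black"],
                      [race == "Hispanic"])
    eta = float((x @ fit.beta)[0])
    if integrate_random_effect:
        return float(_integrated_prob(np.array([eta]), fit.sigma_u, fit.n_nodes)[0])
    return float(expit(eta))


def _subgroup_mean_prob(fit: LogitFit, ages, sex: str, race: str,
                        integrate: bool, beta=None) -> float:
    beta = fit.beta if beta is None else beta
    x = design_matrix(ages, np.full(len(ages), sex == "woman"),
                      np.full(len(ages), race == "Black"),
                      np.full(len(ages), race == "Hispanic"))
    eta = x @ beta
    p = _integrated_prob(eta, fit.sigma_u, fit.n_nodes) if integrate else expit(eta)
    return float(np.mean(p))


def subgroup_table(fits: dict, panel: pd.DataFrame,
                   integrate_random_effect: bool = True,
                   ci: str = "bootstrap", n_boot: int = 1000,
                   level: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Average predicted probabilities by sex-by-race subgroup.

    Averages each fit's prediction over the subgroup's observed age
    distribution.  Intervals come from a parametric bootstrap of the
    coefficient sampling distribution (default) or the delta method
    (``ci="delta"``).  The five stay probabilities are derived by
    complement within each origin state, so each origin's destination
    probabilities sum to 1 exactly.
    """
    if ci not in ("bootstrap", "delta", "none"):
        raise ValueError(f"unknown ci method {ci!r}")
    missing = [n for n in PARAM_NAMES if n not in fits]
    if missing:
        raise ValueError(f"missing fits for transition(s): {missing}")
    rng = np.random.default_rng(seed)
    alpha = 1.0 - level
    zcrit = float(-_norm_ppf(alpha / 2))

    subgroups = (panel[["sex", "race"]].drop_duplicates()
                 .sort_values(["sex", "race"]).itertuples(index=False))
    records = []
    for sex, race in subgroups:
        mask = (panel["sex"] == sex) & (panel["race"] == race)
        ages = panel.loc[mask, "age"].to_numpy(dtype=float)
        if ages.size == 0:
            logger.warning("empty subgroup cell (%s, %s); omitted", sex, race)
            continue
        points: dict[str, float] = {}
        boots: dict[str, np.ndarray] = {}
        variances: dict[str, float] = {}
        for name in PARAM_NAMES:
            fit = fits[name]
            points[name] = _subgroup_mean_prob(
                fit, ages, sex, race, integrate_random_effect)
            if ci == "bootstrap":
                draws = rng.multivariate_normal(fit.beta, fit.cov_beta, size=n_boot)
                boots[name] = np.array([
                    _subgroup_mean_prob(fit, ages, sex, race,
                                        integrate_random_effect, beta=b)
                    for b in draws
                ])
            elif ci == "delta":
                variances[name] = _delta_variance(
                    fit, ages, sex, race, integrate_random_effect)
        for name in PARAM_NAMES:
            lo = hi = np.nan
            if ci == "bootstrap":
                lo, hi = np.quantile(boots[name], [alpha / 2, 1 - alpha / 2])
            elif ci == "delta":
                sd = np.sqrt(variances[name])
                lo, hi = points[name] - zcrit * sd, points[name] + zcrit * sd
            records.append({
                "sex": sex, "race": race, "transition": name,
                "probability": points[name],
                "lower": max(lo, 0.0) if np.isfinite(lo) else lo,
                "upper": min(hi, 1.0) if np.isfinite(hi) else hi,
                "derived_stay": False,
            })
        # stays by complement within each origin state
        for origin in STATES:
            outflows = [n for n in PARAM_NAMES if n.startswith(origin + "->")]
            stay_point = 1.0 - sum(points[n] for n in outflows)
            lo = hi = np.nan
            if ci == "bootstrap":
                stay_draws = 1.0 - np.sum([boots[n] for n in outflows], axis=0)
                lo, hi = np.quantile(stay_draws, [alpha / 2, 1 - alpha / 2])
            elif ci == "delta":
                sd = np.sqrt(sum(variances[n] for n in outflows))
                lo, hi = stay_point - zcrit * sd, stay_point + zcrit * sd
            records.append({
                "sex": sex, "race": race, "transition": f"{origin}->{origin}",
                "probability": stay_point,
                "lower": max(lo, 0.0) if np.isfinite(lo) else lo,
                "upper": min(hi, 1.0) if np.isfinite(hi) else hi,
                "derived_stay": True,
            })
    return pd.DataFrame.from_records(records)


def _delta_variance(fit: LogitFit, ages, sex, race, integrate) -> float:
    x = design_matrix(ages, np.full(len(ages), sex == "woman"),
                      np.full(len(ages), race == "Black"),
                      np.full(len(ages), race == "Hispanic"))
    eta = x @ fit.beta
    if integrate and fit.sigma_u > 0:
        z, w = hermgauss(fit.n_nodes)
        lin = eta[:, None] + np.sqrt(2.0) * fit.sigma_u * z
        dp = (expit(lin) * (1 - expit(lin))) @ (w / np.sqrt(np.pi))
    else:
        dp = expit(eta) * (1 - expit(eta))
    grad = (dp[:, None] * x).mean(axis=0)
    return float(grad @ fit.cov_beta @ grad)


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def params_from_subgroup_table(table: pd.DataFrame, sex: str,
                               race: str) -> TransitionParameters:
    """The 11 non-stay subgroup probabilities as a parameter object."""
    sub = table[(table["sex"] == sex) & (table["race"] == race)
                & ~table["derived_stay"]]
    if len(sub) != len(PARAM_NAMES):
        raise ValueError(f"subgroup ({sex}, {race}) not fully present in table")
    d = dict(zip(sub["transition"], sub["probability"]))
    return TransitionParameters.from_dict(d, label=f"{race} {sex}")


def simulate_logit_outcomes(X, beta, sigma_u, groups, rng) -> np.ndarray:
    """Draw 0/1 outcomes from the random-intercept logistic model.

    Utility for recovery experiments: one intercept per unique group,
    shared across that group's rows.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    uniq, inv = np.unique(groups, return_inverse=True)
    u = rng.normal(0.0, sigma_u, size=uniq.size)
    p = expit(X @ np.asarray(beta, dtype=float) + u[inv])
    return (rng.random(X.shape[0]) < p).astype(float)
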