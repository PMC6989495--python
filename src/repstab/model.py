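"""Random-intercept mixed-effects logistic regression for single-trial memory.

The probability of correctly recognising a pair is modelled as

    P(y_ij = 1 | u_j) = logistic(beta . x_ij + u_j),   u_j ~ N(0, sigma_u^2)

with one random intercept per subject.  The marginal likelihood integrates
each subject's intercept out by adaptive Gauss-Hermite quadrature (the
integrand is re-centred on its mode and re-scaled by the curvature there, so
20 nodes are ample even for large clusters).  Coefficients are tested with
Wald z statistics and reported as odds ratios with 95% CIs; model selection
across candidate fixed effects is forward-stepwise on AIC with a VIF screen
(VIF > 5 flags multicollinearity).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats
from scipy.special import expit, log_expit

__all__ = ["ModelFit", "fit_random_intercept_logistic", "stepwise_aic", "vif",
           "build_design", "standardize"]

log = logging.getLogger(__name__)

_SEPARATION_BOUND = 15.0


def standardize(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Return a copy with the named columns scaled to mean 0, SD 1."""
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return out


def build_design(table: pd.DataFrame, terms) -> np.ndarray:
    """Design matrix (no intercept column) for main effects and ``a:b`` products.

    Interaction columns are products of the (already standardized) main
    effects and are deliberately not re-standardized, so odds ratios stay
    interpretable per SD of the main effects.
    """
    cols = []
    for term in terms:
        if ":" in term and term not in table.columns:
            a, b = term.split(":", 1)
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[term].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


@dataclass
class ModelFit:
    terms: list[str]
    params: np.ndarray          # intercept + coefficients
    se: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    odds_ratio: np.ndarray
    or_ci: np.ndarray           # (k, 2)
    sigma_u: float
    loglik: float
    aic: float
    vif: dict
    n_trials: int
    n_subjects: int
    n_quad: int
    converged: bool
    unstable: bool = False

    def summary(self) -> pd.DataFrame:
        names = ["intercept"] + list(self.terms)
        return pd.DataFrame({
            "term": names,
            "estimate": self.params,
            "se": self.se,
            "wald_z": self.wald_z,
            "p": self.p_values,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci[:, 0],
            "or_ci_high": self.or_ci[:, 1],
        })


# --------------------------------------------------------------------------
# likelihood


def _group_index(subjects: np.ndarray):
    uniq, inv = np.unique(subjects, return_inverse=True)
    return uniq, inv


def _loglik_parts(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                  inv: np.ndarray, n_sub: int, nodes: np.ndarray,
                  weights: np.ndarray, newton_iter: int = 12):
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    theta = (intercept, beta..., log sigma_u).  Per subject the integrand
    exp(h(u)) with h(u) = sum_i loglik_i(u) - u^2 / (2 sigma^2) is re-centred
    on its mode u_hat (found by Newton; h is strictly concave) and scaled by
    tau = (-h''(u_hat))^(-1/2).
    """
    beta = theta[:-1]
    sigma = np.exp(theta[-1])
    eta0 = X @ beta
    sign = 2.0 * y - 1.0  # loglik_i(u) = log_expit(sign * (eta0 + u))

    # Newton for the per-subject mode of h
    u = np.zeros(n_sub)
    for _ in range(newton_iter):
        eta = eta0 + u[inv]
        p = expit(eta)
        grad = np.bincount(inv, weights=y - p, minlength=n_sub) - u / sigma ** 2
        hess = -np.bincount(inv, weights=p * (1 - p), minlength=n_sub) - 1.0 / sigma ** 2
        step = grad / hess
        u = u - step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[inv]
    p = expit(eta)
    h2 = -np.bincount(inv, weights=p * (1 - p), minlength=n_sub) - 1.0 / sigma ** 2
    tau = 1.0 / np.sqrt(-h2)

    # h at the shifted nodes u_q = u_hat + sqrt(2) tau x_q
    uq = u[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]   # (S, Q)
    eta_q = eta0[:, None] + uq[inv]                                  # (N, Q)
    ll_q = log_expit(sign[:, None] * eta_q)
    h_q = np.zeros((n_sub, len(nodes)))
    np.add.at(h_q, inv, ll_q)
    h_q -= uq ** 2 / (2.0 * sigma ** 2)

    log_w = np.log(weights) + nodes ** 2
    per_sub = (np.log(np.sqrt(2.0) * tau) - np.log(np.sqrt(2 * np.pi) * sigma)
               + _logsumexp(h_q + log_w[None, :], axis=1))
    return per_sub.sum()


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def marginal_loglik(params: np.ndarray, sigma_u: float, table: pd.DataFrame,
                    terms, outcome: str = "outcome", group: str = "subject",
                    n_quad: int = 20) -> float:
    """Log-likelihood of given coefficients (public hook for oracle tests)."""
    X = np.column_stack([np.ones(len(table)), build_design(table, terms)])
    y = table[outcome].to_numpy(dtype=float)
    _, inv = _group_index(table[group].to_numpy())
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    theta = np.r_[params, np.log(max(sigma_u, 1e-10))]
    return _loglik_parts(theta, X, y, inv, inv.max() + 1, nodes, weights)


def fit_random_intercept_logistic(table: pd.DataFrame, terms,
                                  outcome: str = "outcome",
                                  group: str = "subject",
                                  n_quad: int = 20,
                                  compute_vif: bool = True) -> ModelFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    ``terms`` are predictor columns of ``table`` (interactions as ``a:b``);
    an intercept and the subject random effect are always included.
    """
    y = table[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; model not identified")
    subjects = table[group].to_numpy()
    uniq, inv = _group_index(subjects)
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects for a random intercept")
    Xmain = build_design(table, terms)
    X = np.column_stack([np.ones(len(table)), Xmain])
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    n_sub = len(uniq)

    def nll(theta):
        return -_loglik_parts(theta, X, y, inv, n_sub, nodes, weights)

    x0 = np.zeros(X.shape[1] + 1)
    x0[0] = np.log(y.mean() / (1 - y.mean()))
    x0[-1] = np.log(0.5)
    bounds = [(-50, 50)] * X.shape[1] + [(np.log(1e-6), np.log(20.0))]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    theta = res.x
    loglik = -res.fun
    k = X.shape[1] + 1  # coefficients + sigma_u

    hess = _numeric_hessian(nll, theta)
    se_all = _safe_se(hess)
    params = theta[:-1]
    se = se_all[:-1]
    wald_z = np.where(se > 0, params / se, np.nan)
    p_values = 2 * sstats.norm.sf(np.abs(wald_z))
    or_ci = np.column_stack([np.exp(params - 1.96 * se), np.exp(params + 1.96 * se)])
    unstable = bool(np.any(np.abs(params) > _SEPARATION_BOUND))
    if unstable:
        log.warning("fit flagged unstable: |estimate| > %.0f suggests separation",
                    _SEPARATION_BOUND)
    vifs = vif(table, list(terms)) if (compute_vif and len(terms) >= 2) else {}
    return ModelFit(terms=list(terms), params=params, se=se, wald_z=wald_z,
                    p_values=p_values, odds_ratio=np.exp(params), or_ci=or_ci,
                    sigma_u=float(np.exp(theta[-1])), loglik=float(loglik),
                    aic=float(2 * k - 2 * loglik), vif=vifs,
                    n_trials=len(table), n_subjects=n_sub, n_quad=n_quad,
                    converged=bool(res.success), unstable=unstable)


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    hess = np.empty((n, n))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return hess


def _safe_se(hess: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov).copy()
        diag[diag < 0] = np.nan
        return np.sqrt(diag)
    except np.linalg.LinAlgError:
        return np.full(hess.shape[0], np.nan)


# --------------------------------------------------------------------------
# multicollinearity and model selection


def vif(table: pd.DataFrame, predictors) -> dict:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    Each predictor (interaction terms allowed as ``a:b``) is regressed on
    the others plus an intercept; exact collinearity yields +inf.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors for VIF")
    X = build_design(table, predictors)
    out = {}
    n = X.shape[0]
    for j, name in enumerate(predictors):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        target = X[:, j]
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float(1.0 / (1.0 - r2)) if r2 < 1.0 - 1e-12 else np.inf
    return out


def stepwise_aic(table: pd.DataFrame, candidate_terms, outcome: str = "outcome",
                 group: str = "subject", vif_limit: float = 5.0,
                 n_quad: int = 20) -> tuple[ModelFit, list[dict]]:
    """Forward-stepwise selection on AIC over candidate fixed effects.

    Starting from the intercept + random-intercept model, the candidate that
    lowers AIC the most is added until no addition lowers it.  Candidates
    whose addition pushes any VIF above ``vif_limit`` are screened out before
    fitting; failed fits are skipped with a log entry.  Returns the selected
    fit and the full selection trace.
    """
    candidate_terms = list(candidate_terms)
    if not candidate_terms:
        raise ValueError("candidate list is empty")
    selected: list[str] = []
    current = fit_random_intercept_logistic(table, selected, outcome, group,
                                            n_quad, compute_vif=False)
    trace = [{"terms": [], "aic": current.aic, "action": "start"}]
    remaining = candidate_terms.copy()
    while remaining:
        best = None
        for term in remaining:
            trial = selected + [term]
            if len(trial) >= 2:
                vifs = vif(table, trial)
                if max(vifs.values()) > vif_limit:
                    trace.append({"terms": trial, "aic": None,
                                  "action": f"screened (VIF > {vif_limit})"})
                    continue
            try:
                fit = fit_random_intercept_logistic(table, trial, outcome,
                                                    group, n_quad,
                                                    compute_vif=False)
            except Exception as exc:  # noqa: BLE001 - candidate skipped, trace records it
                log.warning("stepwise_aic: candidate %s failed: %s", trial, exc)
                trace.append({"terms": trial, "aic": None, "action": f"failed: {exc}"})
                continue
            trace.append({"terms": trial, "aic": fit.aic, "action": "evaluated"})
            if fit.aic < current.aic and (best is None or fit.aic < best[1].aic):
                best = (term, fit)
        if best is None:
            break
        selected.append(best[0])
        current = best[1]
        remaining.remove(best[0])
        trace.append({"terms": selected.copy(), "aic": current.aic, "action": "added"})
    if selected:
        current = fit_random_intercept_logistic(table, selected, outcome, group,
                                                n_quad, compute_vif=len(selected) >= 2)
    return current, trace
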