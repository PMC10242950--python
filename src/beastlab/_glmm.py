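"""Random-intercept logistic regression by adaptive Gauss-Hermite quadrature.

Maximum-likelihood fit of

    y_ij ~ Bernoulli(logistic(x_ij' beta + u_i)),   u_i ~ N(0, tau00)

with one scalar random intercept per cluster.  The marginal likelihood of
each cluster is a one-dimensional integral, evaluated adaptively: the
integrand's mode is found by (vectorized) Newton iteration, the quadrature
grid is centred and scaled there, and a log-sum-exp keeps the result stable
for extreme linear predictors.  Adaptive placement matters here: with
tau00 ~ 4 and only five observations per cluster, a prior-scaled grid
misplaces the mass and biases the variance estimate.

This is deliberately a minimal engine: one random intercept, logit link,
Wald covariance from a finite-difference Hessian.  Cross-checks against
lme4::glmer live in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

_NEWTON_STEPS = 30


@dataclass
class LogisticMixedResult:
    params: np.ndarray            # fixed-effect coefficients, order of X columns
    cov_params: np.ndarray        # Wald covariance of the fixed effects
    tau00: float                  # random-intercept variance (ML)
    loglik: float
    n_clusters: int
    n_obs: int
    converged: bool
    penalized: bool = False       # separation fallback engaged
    warnings: list = field(default_factory=list)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))


def _cluster_loglik(theta, X, y, first, counts, gh_x, gh_w, penalty=0.0):
    """Sum over clusters of log integral; theta = (beta..., log_sd_u)."""
    beta = theta[:-1]
    sd_u = np.exp(theta[-1])
    var_u = sd_u * sd_u
    eta0 = X @ beta
    n_clusters = len(first)

    # Newton for the mode of  l_i(u) = sum_j [y eta - log(1+e^eta)] - u^2/(2 var).
    u = np.zeros(n_clusters)
    for _ in range(_NEWTON_STEPS):
        eta = eta0 + np.repeat(u, counts)
        p = special.expit(eta)
        g = np.add.reduceat(y - p, first) - u / var_u
        h = -np.add.reduceat(p * (1.0 - p), first) - 1.0 / var_u
        step = g / h
        # Damp: |step| capped to keep Newton in the basin for extreme etas.
        step = np.clip(step, -4.0, 4.0)
        u = u - step
        if np.max(np.abs(step)) < 1e-9:
            break
    eta = eta0 + np.repeat(u, counts)
    p = special.expit(eta)
    h = -np.add.reduceat(p * (1.0 - p), first) - 1.0 / var_u
    scale = 1.0 / np.sqrt(-h)  # Laplace sd at the mode

    # Adaptive nodes: u_ik = mode_i + sqrt(2) * scale_i * x_k.
    nodes = u[:, None] + np.sqrt(2.0) * scale[:, None] * gh_x[None, :]
    eta_k = eta0[:, None] + np.repeat(nodes, counts, axis=0)
    # Bernoulli log-likelihood per observation and node, summed per cluster.
    ll_obs = y[:, None] * eta_k - np.logaddexp(0.0, eta_k)
    ll_cluster = np.add.reduceat(ll_obs, first, axis=0)
    ll_cluster += (
        -0.5 * nodes**2 / var_u
        - 0.5 * np.log(2.0 * np.pi * var_u)
    )
    # log sum_k w_k e^{x_k^2} sqrt(2) scale_i e^{l_i(u_ik)}
    log_w = np.log(gh_w) + gh_x**2
    stacked = ll_cluster + log_w[None, :]
    m = stacked.max(axis=1)
    ll = m + np.log(np.sum(np.exp(stacked - m[:, None]), axis=1))
    ll += 0.5 * np.log(2.0) + np.log(scale)
    total = float(np.sum(ll))
    if penalty > 0.0:
        total -= 0.5 * penalty * float(beta @ beta)
    return total


def _ordinary_logistic_loglik(beta, X, y):
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    cluster_ids: np.ndarray,
    n_quad: int = 21,
    penalty: float = 0.0,
    max_abs_coef: float = 15.0,
) -> LogisticMixedResult:
    """ML fit; columns of X are the fixed effects (include the intercept).

    Rows must be grouped by cluster (they are sorted internally).  If the
    optimizer fails or a coefficient diverges (separation), the model is
    refit with a mild quadratic penalty on the fixed effects and the result
    is flagged ``penalized``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    order = np.argsort(cluster_ids, kind="stable")
    X, y, cluster_ids = X[order], y[order], cluster_ids[order]
    _, first, counts = np.unique(cluster_ids, return_index=True, return_counts=True)
    first = np.sort(first)
    n_clusters, n_obs = len(first), len(y)

    notes: list = []
    if y.min() == y.max():
        # Degenerate outcome: no finite MLE; fall back to a ridge-penalized
        # fit so the pipeline can still report (flagged) estimates.
        notes.append("outcome is constant; penalized-likelihood fallback")
        penalty = max(penalty, 0.1)

    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)

    # Start from ordinary logistic regression (tau00 = 0 limit).
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            start_beta = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=50
            ).params
            start_beta = np.clip(start_beta, -3.0, 3.0)
        except Exception:
            start_beta = np.zeros(X.shape[1])
    theta0 = np.concatenate([start_beta, [np.log(1.0)]])

    def negll(theta, pen):
        return -_cluster_loglik(theta, X, y, first, counts, gh_x, gh_w, pen)

    res = optimize.minimize(
        negll, theta0, args=(penalty,), method="BFGS",
        options={"gtol": 1e-6, "maxiter": 500},
    )
    penalized = penalty > 0.0
    if (not res.success and np.linalg.norm(res.jac) > 1e-2) or \
            np.max(np.abs(res.x[:-1])) > max_abs_coef:
        notes.append(
            "possible separation or non-convergence; refit with ridge penalty 0.1"
        )
        res = optimize.minimize(
            negll, theta0, args=(0.1,), method="BFGS",
            options={"gtol": 1e-6, "maxiter": 500},
        )
        penalized = True

    theta_hat = res.x
    hess = _numeric_hessian(lambda t: negll(t, 0.1 if penalized else penalty), theta_hat)
    k = X.shape[1]
    try:
        cov_all = np.linalg.inv(hess)
        cov_beta = cov_all[:k, :k]
        if np.any(np.diag(cov_beta) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        notes.append("Hessian not positive definite; SEs from pseudo-inverse")
        cov_all = np.linalg.pinv(hess)
        cov_beta = np.abs(cov_all[:k, :k])

    # BFGS sometimes stops on "precision loss" while already at the optimum;
    # accept the fit if the gradient is essentially zero.
    converged = bool(res.success) or float(np.linalg.norm(res.jac)) < 1e-2
    return LogisticMixedResult(
        params=theta_hat[:k],
        cov_params=cov_beta,
        tau00=float(np.exp(2.0 * theta_hat[-1])),
        loglik=-float(negll(theta_hat, 0.0)),
        n_clusters=n_clusters,
        n_obs=n_obs,
        converged=converged,
        penalized=penalized,
        warnings=notes,
    )


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    # Central second differences; good enough for Wald SEs.
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / eps**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * eps**2)
    return H
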