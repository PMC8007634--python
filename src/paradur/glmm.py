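"""Binomial-logit mixed models by Laplace-approximated maximum likelihood.

Fits models of the form

    logit P(y_ij = 1) = x_ij' beta + z_ij' b_i,   b_i ~ N(0, Sigma)

with a small number of random-effect dimensions per group (here: a by-subject
random intercept, optionally plus a random duration slope).  The marginal
likelihood integrates the random effects with a Laplace approximation: per
group, the integrand is maximized over ``b_i`` by Newton's method (globally
convergent here, the penalized Bernoulli log-likelihood being strictly
concave), and the Gaussian curvature correction is applied at the mode.  The
fixed effects and the Cholesky factor of ``Sigma`` are then maximized jointly
with L-BFGS-B.

Aggregated binomial rows (successes out of n at identical covariates) are
supported and make the fits fast enough for parametric bootstrapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln

_LOG_SD_MIN, _LOG_SD_MAX = np.log(1e-3), np.log(50.0)
_ETA_CLIP = 35.0


def _chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular Cholesky factor of Sigma from unconstrained theta.

    Diagonal entries are ``exp`` of their parameters; the strict lower
    triangle is unconstrained.  ``theta`` has q(q+1)/2 entries ordered
    row-wise.
    """
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L


def _theta_size(q: int) -> int:
    return q * (q + 1) // 2


@dataclass
class MixedGLMResult:
    """Fitted binomial mixed model."""

    beta: np.ndarray
    theta: np.ndarray
    cov_re: np.ndarray
    loglike: float
    bic: float
    converged: bool
    n_obs: int  # number of Bernoulli trials
    n_groups: int
    k_params: int
    message: str
    re_modes: np.ndarray  # (n_groups, q) Laplace modes
    x_names: list[str] | None = None

    @property
    def re_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_re))

    @property
    def re_corr(self) -> float | None:
        if self.cov_re.shape[0] < 2:
            return None
        s = self.re_sd
        if np.any(s == 0):
            return 0.0
        return float(self.cov_re[0, 1] / (s[0] * s[1]))


class _LaplaceObjective:
    """Negative Laplace marginal log-likelihood, with warm-started modes."""

    def __init__(self, X, Z, groups, successes, trials):
        self.X = np.asarray(X, float)
        self.Z = np.asarray(Z, float)
        self.groups = np.asarray(groups, int)
        self.y = np.asarray(successes, float)
        self.n = np.asarray(trials, float)
        self.G = int(self.groups.max()) + 1
        self.q = self.Z.shape[1]
        self.b = np.zeros((self.G, self.q))
        # binomial coefficient constant (kept so deviances are comparable
        # across aggregations)
        self.log_binom = float(
            np.sum(gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1))
        )

    def _group_sum(self, w: np.ndarray) -> np.ndarray:
        return np.bincount(self.groups, weights=w, minlength=self.G)

    def _inner_modes(self, beta: np.ndarray, Sigma_inv: np.ndarray):
        """Newton maximization of the penalized log-likelihood per group."""
        X, Z, g, y, n = self.X, self.Z, self.groups, self.y, self.n
        q, G = self.q, self.G
        xb = X @ beta
        b = self.b.copy()
        for _ in range(60):
            eta = np.clip(xb + np.einsum("ij,ij->i", Z, b[g]), -_ETA_CLIP, _ETA_CLIP)
            p = expit(eta)
            resid = y - n * p
            w = n * p * (1.0 - p)
            grad = np.stack(
                [self._group_sum(Z[:, j] * resid) for j in range(q)], axis=1
            ) - b @ Sigma_inv
            H = np.empty((G, q, q))
            for j in range(q):
                for k2 in range(j, q):
                    s = self._group_sum(Z[:, j] * Z[:, k2] * w)
                    H[:, j, k2] = s + Sigma_inv[j, k2]
                    H[:, k2, j] = H[:, j, k2]
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            b += step
            if np.max(np.abs(step)) < 1e-10:
                break
        self.b = b
        eta = np.clip(xb + np.einsum("ij,ij->i", Z, b[g]), -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        w = n * p * (1.0 - p)
        H = np.empty((G, q, q))
        for j in range(q):
            for k2 in range(j, q):
                s = self._group_sum(Z[:, j] * Z[:, k2] * w)
                H[:, j, k2] = s + Sigma_inv[j, k2]
                H[:, k2, j] = H[:, j, k2]
        return b, eta, H

    def loglike(self, params: np.ndarray) -> float:
        p_fix = self.X.shape[1]
        beta = params[:p_fix]
        L = _chol_from_theta(params[p_fix:], self.q)
        Sigma = L @ L.T
        sign, logdet_S = np.linalg.slogdet(Sigma)
        Sigma_inv = np.linalg.inv(Sigma)
        b, eta, H = self._inner_modes(beta, Sigma_inv)
        p = expit(eta)
        ll_data = float(
            np.sum(self.y * np.log(np.clip(p, 1e-300, 1)))
            + np.sum((self.n - self.y) * np.log(np.clip(1 - p, 1e-300, 1)))
        ) + self.log_binom
        quad = float(np.einsum("gi,ij,gj->", b, Sigma_inv, b))
        _, logdet_H = np.linalg.slogdet(H)
        return ll_data - 0.5 * quad - 0.5 * self.G * logdet_S - 0.5 * float(
            np.sum(logdet_H)
        )

    def __call__(self, params: np.ndarray) -> float:
        return -self.loglike(params)


def fit_binomial_mixed(
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    start_beta: np.ndarray | None = None,
    start_theta: np.ndarray | None = None,
    x_names: list[str] | None = None,
    maxiter: int = 300,
) -> MixedGLMResult:
    """Fit the binomial-logit mixed model.

    Parameters
    ----------
    X, Z : fixed- and random-effect design matrices (rows aligned).
    groups : integer group codes 0..G-1 (subjects).
    successes, trials : aggregated binomial responses per row.
    start_beta, start_theta : optional warm starts (bootstrap refits).
    """
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    obj = _LaplaceObjective(X, Z, groups, successes, trials)
    p_fix, q = X.shape[1], obj.q

    if start_beta is None:
        import statsmodels.api as sm

        glm = sm.GLM(
            np.column_stack([obj.y, obj.n - obj.y]), X, family=sm.families.Binomial()
        )
        try:
            start_beta = np.asarray(glm.fit().params)
        except Exception:
            start_beta = np.zeros(p_fix)
    if start_theta is None:
        start_theta = np.zeros(_theta_size(q))  # SDs of 1, no correlation

    x0 = np.concatenate([start_beta, start_theta])
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * p_fix
    k = 0
    for i in range(q):
        for j in range(i + 1):
            bounds.append((_LOG_SD_MIN, _LOG_SD_MAX) if i == j else (-50.0, 50.0))
            k += 1
    res = minimize(
        obj,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x[:p_fix]
    theta = res.x[p_fix:]
    L = _chol_from_theta(theta, q)
    ll = -res.fun
    n_obs = int(np.sum(obj.n))
    k_params = p_fix + _theta_size(q)
    bic = -2.0 * ll + k_params * np.log(n_obs)
    return MixedGLMResult(
        beta=beta,
        theta=theta,
        cov_re=L @ L.T,
        loglike=float(ll),
        bic=float(bic),
        converged=bool(res.success),
        n_obs=n_obs,
        n_groups=obj.G,
        k_params=k_params,
        message=str(res.message),
        re_modes=obj.b.copy(),
        x_names=x_names,
    )


def simulate_from_fit(
    result: MixedGLMResult,
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    trials: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Parametric-bootstrap responses: new random effects, new binomials."""
    G = result.n_groups
    q = Z.shape[1]
    L = np.linalg.cholesky(result.cov_re + 1e-12 * np.eye(q))
    b = rng.standard_normal((G, q)) @ L.T
    eta = X @ result.beta + np.einsum("ij,ij->i", Z, b[np.asarray(groups, int)])
    p = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    return rng.binomial(np.asarray(trials, int), p).astype(float)
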