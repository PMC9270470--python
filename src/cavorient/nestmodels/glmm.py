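"""Maximum-likelihood GLMM with a single random intercept.

The marginal likelihood integrates the cluster random effect out of a
Poisson (log link) or binomial (logit link) likelihood with Gauss-Hermite
quadrature — the same Laplace-class approximation family used by standard
mixed-model software. The variance component is parameterized by the
standard deviation ``sigma >= 0`` so a zero estimate (a singular fit) is
attainable exactly; ``tau00 = sigma**2``.

Analytic gradients keep repeated fits (model selection, simulation studies)
fast; standard errors come from a finite-difference Hessian of the analytic
gradient at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from cavorient.errors import ConvergenceError

_ETA_CLIP = 30.0  # linear predictors beyond this are numerically saturated


@dataclass(frozen=True)
class GLMMFit:
    beta: np.ndarray
    sigma: float
    loglik: float
    cov_beta: np.ndarray
    se_beta: np.ndarray
    converged: bool
    n_obs: int
    n_groups: int

    @property
    def tau00(self) -> float:
        return float(self.sigma**2)


class _Marginal:
    """Negative marginal log-likelihood and gradient for one model."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        groups: np.ndarray,
        family: str,
        trials: np.ndarray | None,
        n_quad: int,
    ) -> None:
        if family not in ("poisson", "binomial"):
            raise ValueError(f"unknown family {family!r}")
        if family == "binomial" and trials is None:
            raise ValueError("binomial family requires trials")
        order = np.argsort(groups, kind="stable")
        self.X = np.asarray(X, dtype=float)[order]
        self.y = np.asarray(y, dtype=float)[order]
        self.trials = None if trials is None else np.asarray(trials, dtype=float)[order]
        g = np.asarray(groups)[order]
        self.starts = np.concatenate([[0], 1 + np.flatnonzero(g[1:] != g[:-1])])
        self.n_groups = self.starts.size
        self.family = family
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self.z = nodes * np.sqrt(2.0)  # standard-normal abscissae
        self.logw = np.log(weights / np.sqrt(np.pi))
        if family == "poisson":
            self.const = -special.gammaln(self.y + 1.0).sum()
        else:
            m = self.trials
            self.const = float(
                (special.gammaln(m + 1) - special.gammaln(self.y + 1) - special.gammaln(m - self.y + 1)).sum()
            )

    def _node_loglik(self, eta_nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-observation-per-node loglik (without constants) and d/d eta."""
        E = np.clip(eta_nodes, -_ETA_CLIP, _ETA_CLIP)
        if self.family == "poisson":
            mu = np.exp(E)
            ll = self.y[:, None] * E - mu
            dll = self.y[:, None] - mu
        else:
            m = self.trials[:, None]
            ll = self.y[:, None] * E - m * np.logaddexp(0.0, E)
            dll = self.y[:, None] - m * special.expit(E)
        return ll, dll

    def value_and_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        beta, sigma = params[:-1], params[-1]
        eta = self.X @ beta
        E = eta[:, None] + sigma * self.z[None, :]
        ll, dll = self._node_loglik(E)
        S = np.add.reduceat(ll, self.starts, axis=0) + self.logw[None, :]  # (J, q)
        smax = S.max(axis=1, keepdims=True)
        expS = np.exp(S - smax)
        sumexp = expS.sum(axis=1, keepdims=True)
        lj = smax[:, 0] + np.log(sumexp[:, 0])
        loglik = float(lj.sum() + self.const)

        A = expS / sumexp  # posterior node weights per group (J, q)
        A_obs = np.repeat(A, np.diff(np.append(self.starts, self.y.size)), axis=0)  # (n, q)
        W = dll * A_obs
        g_beta = self.X.T @ W.sum(axis=1)
        g_sigma = float((W * self.z[None, :]).sum())
        grad = np.concatenate([g_beta, [g_sigma]])
        return -loglik, -grad

    def loglik(self, params: np.ndarray) -> float:
        return -self.value_and_grad(params)[0]


def fit_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    family: str,
    trials: np.ndarray | None = None,
    start_beta: np.ndarray | None = None,
    start_sigma: float = 0.5,
    n_quad: int = 21,
) -> GLMMFit:
    """Fit the random-intercept GLMM by marginal maximum likelihood."""
    marg = _Marginal(X, y, groups, family, trials, n_quad)
    p = X.shape[1]
    beta0 = np.zeros(p) if start_beta is None else np.asarray(start_beta, dtype=float)
    x0 = np.concatenate([beta0, [start_sigma]])
    bounds = [(None, None)] * p + [(0.0, None)]
    res = optimize.minimize(
        marg.value_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        # one restart from a flat start before giving up
        res2 = optimize.minimize(
            marg.value_and_grad,
            np.concatenate([np.zeros(p), [0.2]]),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        if res2.fun < res.fun:
            res = res2
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"GLMM optimization failed: {res.message}")

    params = res.x
    cov = _hessian_cov(marg, params)
    cov_beta = cov[:p, :p]
    se_beta = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    return GLMMFit(
        beta=params[:p].copy(),
        sigma=float(params[p]),
        loglik=float(-res.fun),
        cov_beta=cov_beta,
        se_beta=se_beta,
        converged=bool(res.success),
        n_obs=int(np.asarray(y).size),
        n_groups=marg.n_groups,
    )


def _hessian_cov(marg: _Marginal, params: np.ndarray) -> np.ndarray:
    """Observed-information covariance via central differences of the gradient."""
    k = params.size
    H = np.zeros((k, k))
    at_boundary = params[-1] < 1e-8
    for j in range(k):
        h = 1e-5 * max(1.0, abs(params[j]))
        if j == k - 1 and at_boundary:
            # one-sided at the sigma >= 0 boundary
            g1 = marg.value_and_grad(_bump(params, j, 2 * h))[1]
            g0 = marg.value_and_grad(params)[1]
            H[j] = (g1 - g0) / (2 * h)
        else:
            gp = marg.value_and_grad(_bump(params, j, h))[1]
            gm = marg.value_and_grad(_bump(params, j, -h))[1]
            H[j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def _bump(params: np.ndarray, j: int, h: float) -> np.ndarray:
    out = params.copy()
    out[j] += h
    return out
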