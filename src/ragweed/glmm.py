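"""Generalised linear mixed models with one Gaussian random intercept.

Maximum-likelihood fitting of Bernoulli-logit and Poisson-log GLMs with a
per-group random intercept u_g ~ N(0, sigma^2), the group likelihood
integrated by the Laplace approximation.  With a single grouping factor the
integral factorises over groups and each inner mode is a one-dimensional
Newton solve, so the whole fit is a small smooth optimisation over
(fixed effects, log sigma).

The marginal log-likelihood contribution of group g at its mode u* is

    sum_i l(eta_i + u*) - u*^2 / (2 sigma^2) - 0.5 * log(1 + sigma^2 H_g)

with H_g the negative second derivative of the data log-likelihood at u*.
As sigma -> 0 this collapses exactly to the plain GLM log-likelihood, which
the tests exploit as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = ["RandomInterceptGLMM", "GLMMResults"]

_FAMILIES = ("binomial", "poisson")
# |linear predictor| beyond this is treated as complete separation
_SEPARATION_BOUND = 15.0


def _loglik_terms(family: str, y: np.ndarray, eta: np.ndarray):
    """(log-lik, d/d eta, d2/d eta2) elementwise for the canonical link."""
    if family == "binomial":
        # l = y*eta - log(1 + e^eta); stable via logaddexp
        ll = y * eta - np.logaddexp(0.0, eta)
        p = special.expit(eta)
        return ll, y - p, -p * (1.0 - p)
    # poisson, log link: l = y*eta - e^eta - log(y!)
    mu = np.exp(eta)
    ll = y * eta - mu - special.gammaln(y + 1.0)
    return ll, y - mu, -mu


@dataclass
class GLMMResults:
    """ML estimates for a random-intercept GLM."""

    params: np.ndarray  # fixed effects
    sigma: float  # random-intercept SD
    loglik: float
    cov_params: np.ndarray | None  # covariance of (fixed effects, log sigma)
    ranef_modes: dict  # group -> conditional mode of u
    family: str
    n_obs: int
    n_groups: int
    converged: bool
    boundary: bool  # separation / parameter at boundary: SEs unreliable
    exog_names: list[str] = field(default_factory=list)

    def bse(self) -> np.ndarray:
        if self.cov_params is None:
            return np.full(self.params.shape, np.nan)
        return np.sqrt(np.diag(self.cov_params)[: len(self.params)])

    def predict_linear(self, x_row: Sequence[float]) -> float:
        """Linear predictor at random effect 0."""
        return float(np.dot(np.asarray(x_row, dtype=float), self.params))

    def predict_response(self, x_row: Sequence[float]) -> float:
        """Response-scale prediction at random effect 0."""
        eta = self.predict_linear(x_row)
        return float(special.expit(eta)) if self.family == "binomial" else float(np.exp(eta))

    def summary(self) -> str:
        se = self.bse()
        lines = [
            f"Random-intercept GLMM ({self.family}, Laplace)",
            f"  n obs {self.n_obs}, n groups {self.n_groups}, "
            f"loglik {self.loglik:.3f}, sigma_site {self.sigma:.4f}",
        ]
        for name, b, s in zip(self.exog_names, self.params, se):
            lines.append(f"  {name:<20s} {b:10.4f}  (se {s:.4f})")
        if self.boundary:
            lines.append("  [boundary fit: separation or variance at 0; SEs unreliable]")
        return "\n".join(lines)


class RandomInterceptGLMM:
    """Bernoulli-logit or Poisson-log GLM with a Gaussian random intercept.

    Parameters
    ----------
    endog : response vector ({0,1} for binomial, counts for poisson)
    exog : fixed-effects design matrix (include the intercept column)
    groups : group label per observation (the random-intercept factor)
    family : "binomial" or "poisson"
    """

    def __init__(
        self,
        endog: Sequence[float],
        exog: np.ndarray,
        groups: Sequence,
        family: str = "binomial",
        exog_names: Sequence[str] | None = None,
    ):
        if family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        self.y = np.asarray(endog, dtype=float)
        self.X = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("endog and exog lengths differ")
        self.family = family
        labels = np.asarray(groups)
        self.group_labels, self.group_idx = np.unique(labels, return_inverse=True)
        self.n_groups = len(self.group_labels)
        self._rows_by_group = [
            np.flatnonzero(self.group_idx == g) for g in range(self.n_groups)
        ]
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.X.shape[1])]
        )

    # -- inner problem: conditional mode of u_g given params ----------------
    def _group_mode(self, rows: np.ndarray, beta: np.ndarray, sigma2: float) -> tuple[float, float, float]:
        """Newton solve for u*; returns (u*, data loglik at u*, H = -sum d2l)."""
        eta0 = self.X[rows] @ beta
        y = self.y[rows]
        u = 0.0
        for _ in range(100):
            ll, d1, d2 = _loglik_terms(self.family, y, eta0 + u)
            grad = d1.sum() - u / sigma2
            hess = d2.sum() - 1.0 / sigma2
            step = -grad / hess
            # damped Newton: the objective is strictly concave, halving converges
            while abs(step) > 50.0:
                step /= 2.0
            u_new = u + step
            if abs(step) < 1e-10:
                u = u_new
                break
            u = u_new
        ll, d1, d2 = _loglik_terms(self.family, y, eta0 + u)
        return u, float(ll.sum()), float(-d2.sum())

    def loglike(self, params: np.ndarray) -> float:
        """Laplace marginal log-likelihood at (beta, log sigma)."""
        beta, log_sigma = params[:-1], params[-1]
        sigma2 = np.exp(2.0 * log_sigma)
        total = 0.0
        for rows in self._rows_by_group:
            u, ll, H = self._group_mode(rows, beta, sigma2)
            total += ll - u * u / (2.0 * sigma2) - 0.5 * np.log1p(sigma2 * H)
        return total

    def _loglike_fixed(self, beta: np.ndarray) -> float:
        ll, _, _ = _loglik_terms(self.family, self.y, self.X @ beta)
        return float(ll.sum())

    def _fit_fixed_only(self) -> tuple[np.ndarray, float]:
        """Plain GLM ML (sigma = 0) by Newton iteration on the full data."""
        p = self.X.shape[1]
        beta = np.zeros(p)
        for _ in range(200):
            eta = self.X @ beta
            _, d1, d2 = _loglik_terms(self.family, self.y, eta)
            grad = self.X.T @ d1
            hess = (self.X * d2[:, None]).T @ self.X
            try:
                step = np.linalg.solve(hess, -grad)
            except np.linalg.LinAlgError:
                break
            # trust-region style cap keeps separation from overflowing
            nrm = np.max(np.abs(step))
            if nrm > 5.0:
                step *= 5.0 / nrm
            beta = beta + step
            if np.max(np.abs(step)) < 1e-12:
                break
            beta = np.clip(beta, -2 * _SEPARATION_BOUND, 2 * _SEPARATION_BOUND)
        return beta, self._loglike_fixed(beta)

    def fit(
        self,
        random_effect: bool = True,
        start_sigma: float = 0.3,
        maxiter: int = 2000,
    ) -> GLMMResults:
        """Maximise the (Laplace) likelihood.

        With ``random_effect=False``, or with a single group, the model
        degenerates to the plain GLM and is fitted directly.
        """
        beta0, ll0 = self._fit_fixed_only()
        boundary = bool(np.max(np.abs(beta0)) >= _SEPARATION_BOUND)

        if not random_effect or self.n_groups < 2:
            cov = self._numeric_cov(lambda b: self._loglike_fixed(b), beta0) if not boundary else None
            return GLMMResults(
                params=beta0,
                sigma=0.0,
                loglik=ll0,
                cov_params=cov,
                ranef_modes={g: 0.0 for g in self.group_labels},
                family=self.family,
                n_obs=len(self.y),
                n_groups=self.n_groups,
                converged=True,
                boundary=boundary,
                exog_names=self.exog_names,
            )

        x0 = np.concatenate([beta0, [np.log(start_sigma)]])
        res = optimize.minimize(
            lambda p: -self.loglike(p),
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
        )
        params = res.x
        loglik = -res.fun
        # if the random effect buys nothing, the variance-0 GLM may be the MLE
        variance_at_zero = ll0 >= loglik - 1e-8
        if variance_at_zero:
            params = np.concatenate([beta0, [-np.inf]])
            loglik = ll0
            sigma = 0.0
        else:
            sigma = float(np.exp(params[-1]))
        beta = params[: self.X.shape[1]]
        boundary = boundary or bool(np.max(np.abs(beta)) >= _SEPARATION_BOUND)

        sigma2 = sigma**2
        modes = {}
        for g, rows in enumerate(self._rows_by_group):
            if sigma == 0.0:
                modes[self.group_labels[g]] = 0.0
            else:
                u, _, _ = self._group_mode(rows, beta, sigma2)
                modes[self.group_labels[g]] = u

        cov = None
        if not boundary:
            if variance_at_zero:
                # fixed-effect information from the plain GLM, conditional on sigma=0
                cov_fix = self._numeric_cov(self._loglike_fixed, beta)
                if cov_fix is not None:
                    cov = np.zeros((len(params), len(params)))
                    cov[: len(beta), : len(beta)] = cov_fix
            else:
                cov = self._numeric_cov(self.loglike, params)
        return GLMMResults(
            params=beta,
            sigma=sigma,
            loglik=loglik,
            cov_params=cov,
            ranef_modes=modes,
            family=self.family,
            n_obs=len(self.y),
            n_groups=self.n_groups,
            converged=bool(res.success) or loglik == ll0,
            boundary=boundary,
            exog_names=self.exog_names,
        )

    @staticmethod
    def _numeric_cov(loglike: Callable[[np.ndarray], float], params: np.ndarray) -> np.ndarray | None:
        """Observed-information covariance by central finite differences."""
        k = len(params)
        h = 1e-4 * np.maximum(1.0, np.abs(params))
        H = np.zeros((k, k))
        f0 = loglike(params)
        for i in range(k):
            for j in range(i, k):
                pi, pj = np.zeros(k), np.zeros(k)
                pi[i], pj[j] = h[i], h[j]
                fpp = loglike(params + pi + pj)
                fpm = loglike(params + pi - pj)
                fmp = loglike(params - pi + pj)
                fmm = loglike(params - pi - pj)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            return np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return None


def lr_test(full: GLMMResults, null: GLMMResults, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio chi-square statistic and p-value."""
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    return stat, float(stats.chi2.sf(stat, df))
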