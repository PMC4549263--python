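"""Mixed models with crossed random intercepts.

Compact fitters for the two model families the inference workflow
needs, written for speed under heavy parametric bootstrapping:

* :class:`LinearMixedModel` — Gaussian response, profiled ML/REML
  deviance over the relative random-effect standard deviations
  (``theta = sd_f / sigma``), solved through the q x q penalized
  least-squares system (the profiling strategy popularized by lme4).
* :class:`LogitMixedModel` — Bernoulli response with logit link,
  Laplace approximation: joint Newton optimization of the fixed
  effects and conditional modes, with the variance parameters
  optimized in an outer derivative-free loop.

Because every random effect is an intercept, the indicator structure
of Z lets all cross-products be computed with ``bincount`` instead of
sparse matrix products. Both classes expose ``loglik``, fixed-effect
covariance, conditional modes and ``simulate``/``refit`` for
parametric bootstrap loops. Random slopes are not supported — the
workflow never needs them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit


@dataclass(frozen=True)
class RandomFactor:
    """A grouping factor: integer level codes for every observation."""

    name: str
    codes: np.ndarray  # shape (n,), values in 0..n_levels-1
    n_levels: int

    @classmethod
    def from_labels(cls, name: str, labels) -> "RandomFactor":
        labels = np.asarray(labels)
        uniques, codes = np.unique(labels, return_inverse=True)
        return cls(name=name, codes=codes.astype(np.intp), n_levels=len(uniques))


def interaction_factor(name: str, a, b) -> RandomFactor:
    """The combination factor a:b (one level per observed pair)."""
    pairs = np.char.add(np.char.add(np.asarray(a, dtype=str), ":"),
                        np.asarray(b, dtype=str))
    return RandomFactor.from_labels(name, pairs)


@dataclass
class MixedFit:
    """A fitted mixed model."""

    beta: np.ndarray
    beta_names: list[str]
    theta: np.ndarray  # relative (LMM) or absolute (GLMM) random-effect SDs
    sigma: float  # residual SD (1.0 for the logit model)
    loglik: float
    method: str  # "ML" | "REML" | "Laplace"
    vcov_beta: np.ndarray
    u: np.ndarray  # spherical conditional modes
    n_obs: int
    converged: bool = True

    @property
    def n_params(self) -> int:
        extra = 1 if self.method in ("ML", "REML") else 0  # residual variance
        return len(self.beta) + len(self.theta) + extra

    @property
    def random_sd(self) -> np.ndarray:
        """Random-effect SDs on the response/linear-predictor scale."""
        return self.theta * (self.sigma if self.method in ("ML", "REML") else 1.0)

    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))


class _MixedBase:
    def __init__(self, X, y, factors, beta_names=None):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.n, self.p = self.X.shape
        if len(self.y) != self.n:
            raise ValueError("X and y lengths differ")
        self.factors = list(factors)
        self.beta_names = list(beta_names) if beta_names else [
            f"b{j}" for j in range(self.p)
        ]
        sizes = [f.n_levels for f in self.factors]
        self.q = int(np.sum(sizes)) if sizes else 0
        self.offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
        # per-column owning factor, for expanding theta to column scales
        self.col_factor = (
            np.concatenate([np.full(s, k) for k, s in enumerate(sizes)])
            if sizes else np.zeros(0, dtype=int)
        )
        # flattened pair indices for ZtWZ blocks (upper triangle)
        self._pair_idx = {}
        for i, fi in enumerate(self.factors):
            for j, fj in enumerate(self.factors[i:], start=i):
                self._pair_idx[(i, j)] = fi.codes * fj.n_levels + fj.codes

    def _lam(self, theta):
        if self.q == 0:
            return np.zeros(0)
        return np.asarray(theta, dtype=float)[self.col_factor]

    def _ztwz(self, w=None):
        """Dense q x q matrix Z'WZ via bincount of pair indices."""
        M = np.zeros((self.q, self.q))
        o = self.offsets
        for (i, j), idx in self._pair_idx.items():
            ni, nj = self.factors[i].n_levels, self.factors[j].n_levels
            blk = np.bincount(idx, weights=w, minlength=ni * nj).reshape(ni, nj)
            M[o[i]:o[i + 1], o[j]:o[j + 1]] = blk
            if i != j:
                M[o[j]:o[j + 1], o[i]:o[i + 1]] = blk.T
        return M

    def _ztwx(self, w=None):
        """q x p matrix Z'WX via per-column bincounts."""
        out = np.empty((self.q, self.p))
        o = self.offsets
        for k, f in enumerate(self.factors):
            for j in range(self.p):
                col = self.X[:, j] if w is None else self.X[:, j] * w
                out[o[k]:o[k + 1], j] = np.bincount(
                    f.codes, weights=col, minlength=f.n_levels
                )
        return out

    def _ztv(self, v):
        """Z'v via per-factor bincounts."""
        parts = [
            np.bincount(f.codes, weights=v, minlength=f.n_levels)
            for f in self.factors
        ]
        return np.concatenate(parts) if parts else np.zeros(0)

    def _zb(self, b):
        """Z @ b for a stacked coefficient vector b."""
        out = np.zeros(self.n)
        o = self.offsets
        for k, f in enumerate(self.factors):
            out += b[o[k]:o[k + 1]][f.codes]
        return out

    def _random_eta(self, sds, rng):
        eta = np.zeros(self.n)
        for k, f in enumerate(self.factors):
            eta += rng.normal(0.0, sds[k], size=f.n_levels)[f.codes]
        return eta


class LinearMixedModel(_MixedBase):
    """Gaussian LMM with crossed random intercepts, profiled deviance."""

    def __init__(self, X, y, factors, beta_names=None):
        super().__init__(X, y, factors, beta_names)
        self._ZtZ = self._ztwz()
        self._ZtX = self._ztwx()
        self._XtX = self.X.T @ self.X
        self._set_response(self.y)

    def _set_response(self, y):
        self.y = np.asarray(y, dtype=float)
        self._Zty = self._ztv(self.y)
        self._Xty = self.X.T @ self.y
        self._yty = float(self.y @ self.y)

    def _solve(self, theta):
        """Solve the joint penalized normal equations for fixed theta.

        Returns (beta, u, pwrss, logdet_M, logdet_RX, A) where
        logdet_RX is the log-determinant of the profiled fixed-effect
        cross-product X'V0^{-1}X.
        """
        lam = self._lam(theta)
        p, q = self.p, self.q
        if q:
            M = lam[:, None] * self._ZtZ * lam[None, :]
            M[np.diag_indices(q)] += 1.0
            A = np.empty((q + p, q + p))
            A[:q, :q] = M
            A[:q, q:] = lam[:, None] * self._ZtX
            A[q:, :q] = A[:q, q:].T
            A[q:, q:] = self._XtX
            rhs = np.concatenate([lam * self._Zty, self._Xty])
            sol = np.linalg.solve(A, rhs)
            u, beta = sol[:q], sol[q:]
            pwrss = self._yty - rhs @ sol
            _, logdet_M = np.linalg.slogdet(M)
            _, logdet_A = np.linalg.slogdet(A)
            logdet_RX = logdet_A - logdet_M
        else:
            beta = np.linalg.solve(self._XtX, self._Xty)
            u = np.zeros(0)
            pwrss = self._yty - self._Xty @ beta
            logdet_M = 0.0
            _, logdet_RX = np.linalg.slogdet(self._XtX)
        return beta, u, float(max(pwrss, 1e-300)), logdet_M, logdet_RX

    def _deviance(self, theta, method):
        _, _, pwrss, logdet_M, logdet_RX = self._solve(theta)
        n, p = self.n, self.p
        if method == "ML":
            return n * np.log(2 * np.pi * pwrss / n) + logdet_M + n
        return ((n - p) * np.log(2 * np.pi * pwrss / (n - p))
                + logdet_M + logdet_RX + (n - p))

    def fit(self, method: str = "ML", theta0=None, coarse: bool = False) -> MixedFit:
        """Fit by profiled deviance.

        ``coarse=True`` loosens the variance-parameter tolerances for
        warm-started bootstrap refits.
        """
        if method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        k = len(self.factors)
        converged = True
        warm = theta0 is not None
        if k == 0:
            theta = np.zeros(0)
        elif k == 1:
            res = optimize.minimize_scalar(
                lambda t: self._deviance(np.array([abs(t)]), method),
                bounds=(0.0, 100.0), method="bounded",
                options={"xatol": 1e-4 if coarse else 1e-6},
            )
            theta = np.array([abs(res.x)])
        else:
            x0 = np.ones(k) if theta0 is None else np.asarray(theta0, dtype=float)
            opts = (
                {"xatol": 1e-3, "fatol": 1e-6, "maxiter": 400}
                if coarse
                else {"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000}
            )
            res = optimize.minimize(
                lambda th: self._deviance(np.abs(th), method), x0,
                method="Nelder-Mead",
                options={**opts,
                         "initial_simplex": _initial_simplex(x0, 0.15 if warm else 0.5)},
            )
            theta = np.abs(res.x)
            converged = bool(res.success) or coarse
        beta, u, pwrss, logdet_M, logdet_RX = self._solve(theta)
        dof = self.n if method == "ML" else self.n - self.p
        sigma2 = pwrss / dof
        loglik = -0.5 * self._deviance(theta, method)
        # vcov(beta) = sigma^2 (X'V0^{-1}X)^{-1}, the lower-right Schur
        # complement of the joint system
        if self.q:
            lam = self._lam(theta)
            M = lam[:, None] * self._ZtZ * lam[None, :]
            M[np.diag_indices(self.q)] += 1.0
            LZX = lam[:, None] * self._ZtX
            RX = self._XtX - LZX.T @ np.linalg.solve(M, LZX)
        else:
            RX = self._XtX
        vcov = sigma2 * np.linalg.inv(RX)
        return MixedFit(
            beta=beta, beta_names=list(self.beta_names), theta=theta,
            sigma=float(np.sqrt(sigma2)), loglik=float(loglik), method=method,
            vcov_beta=vcov, u=u, n_obs=self.n, converged=converged,
        )

    def simulate(self, fit: MixedFit, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model's distribution."""
        eta = self.X @ fit.beta + self._random_eta(fit.random_sd, rng)
        return eta + rng.normal(0.0, fit.sigma, size=self.n)

    def refit(self, y_new, method: str = "ML", theta0=None,
              coarse: bool = False) -> MixedFit:
        old = self.y, self._Zty, self._Xty, self._yty
        try:
            self._set_response(y_new)
            return self.fit(method=method, theta0=theta0, coarse=coarse)
        finally:
            self.y, self._Zty, self._Xty, self._yty = old

    def conditional_modes(self, fit: MixedFit) -> dict[str, np.ndarray]:
        """BLUPs per factor on the response scale."""
        lam = self._lam(fit.theta)
        b = lam * fit.u
        o = self.offsets
        return {f.name: b[o[k]:o[k + 1]] for k, f in enumerate(self.factors)}


class LogitMixedModel(_MixedBase):
    """Bernoulli-logit GLMM with crossed random intercepts (Laplace).

    ``theta`` holds the random-effect SDs directly (no residual scale).
    The fixed effects and conditional modes are optimized jointly by
    Newton's method inside each evaluation of the Laplace deviance, so
    the outer optimization matches the fast joint-mode scheme
    (lme4's ``nAGQ=0``) rather than adaptive quadrature.
    """

    def __init__(self, X, y, factors, beta_names=None):
        super().__init__(X, y, factors, beta_names)
        if not np.all((self.y == 0) | (self.y == 1)):
            raise ValueError("response must be binary 0/1")

    def _penalized(self, beta, u, lam):
        eta = self.X @ beta + (self._zb(lam * u) if self.q else 0.0)
        ll = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(u @ u), eta

    def _inner(self, theta, beta, u, max_iter=60, tol=1e-11):
        """Newton optimization of the joint penalized log-likelihood."""
        lam = self._lam(theta)
        p, q = self.p, self.q
        f, eta = self._penalized(beta, u, lam)
        H = None
        for _ in range(max_iter):
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-12, None)
            r = self.y - mu
            g = np.concatenate([self.X.T @ r, lam * self._ztv(r) - u]) if q else (
                self.X.T @ r
            )
            H = np.empty((p + q, p + q))
            H[:p, :p] = self.X.T @ (self.X * w[:, None])
            if q:
                ZtWX = self._ztwx(w)  # q x p
                H[:p, p:] = (ZtWX * lam[:, None]).T
                H[p:, :p] = H[:p, p:].T
                Huu = lam[:, None] * self._ztwz(w) * lam[None, :]
                Huu[np.diag_indices(q)] += 1.0
                H[p:, p:] = Huu
            if float(np.max(np.abs(g))) < 1e-8 * max(1.0, self.n / 100):
                break
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            t = 1.0
            f_new, eta_new, beta_new, u_new = f, eta, beta, u
            for _ in range(30):
                beta_try = beta + t * step[:p]
                u_try = u + t * step[p:]
                f_try, eta_try = self._penalized(beta_try, u_try, lam)
                if f_try >= f - 1e-12:
                    f_new, eta_new, beta_new, u_new = f_try, eta_try, beta_try, u_try
                    break
                t *= 0.5
            done = abs(f_new - f) < tol * (1 + abs(f))
            beta, u, f, eta = beta_new, u_new, f_new, eta_new
            if done:
                break
        return beta, u, f, H

    def _laplace(self, theta, state):
        beta, u, f, H = self._inner(theta, state["beta"], state["u"])
        state["beta"], state["u"] = beta, u
        if self.q:
            _, logdet = np.linalg.slogdet(H[self.p:, self.p:])
            return f - 0.5 * logdet, beta, u, H
        return f, beta, u, H

    def fit(self, theta0=None, coarse: bool = False) -> MixedFit:
        """Fit by Laplace approximation.

        ``coarse=True`` loosens the outer variance-parameter tolerances;
        intended for warm-started bootstrap refits, where the percentile
        intervals of the fixed effects are insensitive to the last
        digits of theta.
        """
        k = len(self.factors)
        state = {"beta": np.zeros(self.p), "u": np.zeros(self.q)}
        converged = True
        warm = theta0 is not None
        if k == 0:
            theta = np.zeros(0)
        else:
            x0 = np.asarray(theta0, dtype=float) if warm else np.full(k, 0.5)

            def obj(th):
                ll, *_ = self._laplace(np.abs(th), state)
                return -2.0 * ll

            if k == 1:
                res = optimize.minimize_scalar(
                    lambda t: obj(np.array([t])), bounds=(0.0, 30.0),
                    method="bounded",
                    options={"xatol": 1e-3 if coarse else 1e-5},
                )
                theta = np.array([res.x])
            else:
                simplex = _initial_simplex(x0, 0.15 if warm else 0.5)
                opts = (
                    {"xatol": 2e-3, "fatol": 2e-5, "maxiter": 250}
                    if coarse
                    else {"xatol": 1e-4, "fatol": 1e-7, "maxiter": 1000}
                )
                res = optimize.minimize(
                    obj, x0, method="Nelder-Mead",
                    options={**opts, "initial_simplex": simplex},
                )
                theta = np.abs(res.x)
                converged = bool(res.success) or coarse
        ll, beta, u, H = self._laplace(theta, state)
        Hinv = np.linalg.inv(H)
        vcov = Hinv[: self.p, : self.p]
        return MixedFit(
            beta=beta, beta_names=list(self.beta_names), theta=theta,
            sigma=1.0, loglik=float(ll), method="Laplace",
            vcov_beta=vcov, u=u, n_obs=self.n, converged=converged,
        )

    def simulate(self, fit: MixedFit, rng: np.random.Generator) -> np.ndarray:
        eta = self.X @ fit.beta + self._random_eta(fit.theta, rng)
        return (rng.random(self.n) < expit(eta)).astype(float)

    def refit(self, y_new, theta0=None, coarse: bool = False) -> MixedFit:
        y_new = np.asarray(y_new, dtype=float)
        old = self.y
        try:
            self.y = y_new
            return self.fit(theta0=theta0, coarse=coarse)
        finally:
            self.y = old

    def conditional_modes(self, fit: MixedFit) -> dict[str, np.ndarray]:
        lam = self._lam(fit.theta)
        b = lam * fit.u
        o = self.offsets
        return {f.name: b[o[k]:o[k + 1]] for k, f in enumerate(self.factors)}


def _initial_simplex(x0, scale):
    k = len(x0)
    simplex = np.tile(x0, (k + 1, 1))
    for i in range(k):
        simplex[i + 1, i] += max(scale, scale * abs(x0[i]))
    return simplex


def lrt(fit_full: MixedFit, fit_reduced: MixedFit,
        boundary_mixture: bool = False) -> tuple[float, int, float]:
    """Log-likelihood ratio test of a reduced against a full model.

    Returns ``(statistic, df, p)``. By default the p-value uses the
    naive chi-square reference with df equal to the parameter-count
    difference; with ``boundary_mixture=True`` the df=1 variance-
    component case uses the 50:50 mixture of chi-square(0) and
    chi-square(1) appropriate for a variance tested on its boundary.
    """
    from scipy.stats import chi2

    stat = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    df = fit_full.n_params - fit_reduced.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    if boundary_mixture and df == 1:
        p = 0.5 * float(chi2.sf(stat, 1)) if stat > 0 else 1.0
    else:
        p = float(chi2.sf(stat, df))
    return float(stat), int(df), float(p)
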