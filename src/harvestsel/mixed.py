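"""Gaussian mixed-model engine with AR1 residuals and penalized smooths.

The model is

    y = X beta + Z b + e,   b ~ N(0, G),   e ~ N(0, sigma^2 R0(phi))

where ``Z`` is a column-stack of *blocks* (random-intercept indicators and
the range-space columns of penalized smooths), ``G`` is block-diagonal with
one variance ``lambda_j * sigma^2`` per block, and ``R0`` is a unit-variance
AR1 correlation applied to time-ordered rows within residual groups (gaps
are treated as unit steps; rows in different groups are independent).

The marginal likelihood is profiled over ``beta`` and ``sigma^2`` and
maximized over ``(log lambda_1..log lambda_B, atanh phi)`` with L-BFGS-B.
Two structural facts keep this fast: the Woodbury identity reduces all
algebra to q x q systems (q = random-effect columns), and the AR1 precision
is a quadratic polynomial in phi,

    W(phi) = (A0 + phi*A1 + phi^2*A2) / (1 - phi^2),

so every cross-product with data is precomputed once and each likelihood
evaluation costs O(q^3) regardless of n.

Maximum likelihood (not REML) is used throughout so that likelihoods, and
hence AICc, are comparable across candidate models with different fixed
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize

_LOG_2PI = np.log(2.0 * np.pi)
_BIG = 1e10


@dataclass
class RandomBlock:
    """One variance-component block of the random-effects design."""

    name: str
    Z: sparse.csr_matrix

    @property
    def q(self) -> int:
        return self.Z.shape[1]


def ar1_precision(groups: np.ndarray, phi: float) -> tuple[sparse.csr_matrix, float]:
    """Sparse precision and log-determinant of the unit-variance AR1
    correlation matrix over contiguous ``groups`` (reference form; the fitter
    uses the polynomial decomposition instead)."""
    n = groups.shape[0]
    same = groups[1:] == groups[:-1]
    has_prev = np.concatenate([[False], same])
    has_next = np.concatenate([same, [False]])
    isolated = ~(has_prev | has_next)
    interior = has_prev & has_next
    c = 1.0 - phi * phi
    d = np.where(interior, (1.0 + phi * phi) / c, 1.0 / c)
    d[isolated] = 1.0
    off = np.where(same, -phi / c, 0.0)
    w = sparse.diags_array([off, d, off], offsets=[-1, 0, 1], format="csr")
    logdet_r0 = float(same.sum()) * np.log(c)
    return w, logdet_r0


@dataclass
class MixedFitResult:
    beta: np.ndarray
    b: np.ndarray
    cov: np.ndarray           # joint covariance of (beta, b), Bayesian/posterior
    edf: np.ndarray           # per-column effective degrees of freedom
    sigma2: float
    variances: dict           # block name -> variance component (sigma^2 * lambda)
    phi: float
    loglik: float
    n: int
    p: int
    converged: bool
    block_slices: dict = field(default_factory=dict)  # name -> slice into (beta, b)
    n_opt_params: int = 0

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


class _Workspace:
    """Precomputed cross-products for n-free likelihood evaluations."""

    def __init__(self, y, X, blocks, groups, ar1):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        self.n, self.p = X.shape
        self.blocks = blocks
        self.ar1 = ar1
        u = np.column_stack([X, y])  # n x (p+1)
        if blocks:
            z = sparse.hstack([b.Z for b in blocks], format="csr")
            self.qs = np.array([b.q for b in blocks])
        else:
            z = None
            self.qs = np.array([], dtype=int)
        self.q = int(self.qs.sum())

        groups = (
            np.asarray(groups) if groups is not None else np.zeros(self.n, dtype=int)
        )
        same = groups[1:] == groups[:-1]
        self.n_pairs = int(same.sum())

        def products(w):
            wu = u if w is None else w @ u
            zz = (z.T @ (z if w is None else w @ z)).toarray() if z is not None else None
            zu = np.asarray(z.T @ wu) if z is not None else None
            return u.T @ wu, zu, zz

        self.c0 = products(None)
        if ar1:
            n = self.n
            idx = np.arange(n - 1)[same]
            a1 = sparse.coo_matrix(
                (np.full(2 * len(idx), -1.0),
                 (np.concatenate([idx, idx + 1]), np.concatenate([idx + 1, idx]))),
                shape=(n, n),
            ).tocsr()
            has_prev = np.concatenate([[False], same])
            has_next = np.concatenate([same, [False]])
            d2 = np.where(has_prev & has_next, 1.0, 0.0)
            d2[~(has_prev | has_next)] = -1.0
            a2 = sparse.diags_array(d2, format="csr")
            self.c1 = products(a1)
            self.c2 = products(a2)

    def cross_at(self, phi: float):
        """(U'WU, Z'WU, Z'WZ, logdet R0) at AR1 parameter ``phi``."""
        if not self.ar1 or phi == 0.0:
            return (*self.c0, 0.0)
        c = 1.0 - phi * phi
        out = []
        for t0, t1, t2 in zip(self.c0, self.c1, self.c2):
            out.append(None if t0 is None else (t0 + phi * t1 + phi * phi * t2) / c)
        return (*out, self.n_pairs * np.log(c))

    def unpack(self, psi):
        nb = len(self.blocks)
        lam = np.exp(psi[:nb])
        phi = float(np.tanh(psi[nb])) if self.ar1 else 0.0
        return lam, phi

    def neg2ll(self, psi) -> float:
        lam, phi = self.unpack(psi)
        guu, gzu, gzz, logdet_r0 = self.cross_at(phi)
        n, p = self.n, self.p
        try:
            if self.q:
                pen = np.repeat(1.0 / lam, self.qs)
                cf = cho_factor(gzz + np.diag(pen), lower=True)
                g = guu - gzu.T @ cho_solve(cf, gzu)
                logdet_v0 = (
                    logdet_r0
                    + float(self.qs @ np.log(lam))
                    + 2.0 * float(np.log(np.diag(cf[0])).sum())
                )
            else:
                g, logdet_v0 = guu, logdet_r0
            beta = np.linalg.solve(g[:p, :p], g[:p, p])
            rss = float(g[p, p] - g[:p, p] @ beta)
            if not np.isfinite(rss) or rss <= 0:
                return _BIG
            sigma2 = rss / n
            val = n * (_LOG_2PI + np.log(sigma2)) + logdet_v0 + n
            return val if np.isfinite(val) else _BIG
        except (LinAlgError, np.linalg.LinAlgError):
            return _BIG


def fit_mixed(
    y,
    X,
    blocks: list[RandomBlock] | None = None,
    groups=None,
    ar1: bool = False,
    maxiter: int = 200,
    start: np.ndarray | None = None,
) -> MixedFitResult:
    """Fit by maximum likelihood; see module docstring for the model."""
    blocks = blocks or []
    ws = _Workspace(y, X, blocks, groups, ar1)
    ndim = len(blocks) + (1 if ar1 else 0)

    if ndim:
        x0 = np.zeros(ndim) if start is None else np.asarray(start, dtype=float)
        bounds = [(-12.0, 12.0)] * len(blocks) + ([(-4.0, 4.0)] if ar1 else [])
        res = minimize(
            ws.neg2ll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "gtol": 1e-6},
        )
        psi, converged, neg2 = res.x, bool(res.success), float(res.fun)
        if not converged:
            # L-BFGS-B line searches can fail on flat finite-difference
            # gradients near the optimum; a derivative-free polish settles it
            res2 = minimize(
                ws.neg2ll, psi, method="Nelder-Mead",
                options={"maxiter": 200 * ndim, "fatol": 1e-7, "xatol": 1e-6},
            )
            if res2.fun <= neg2:
                psi, neg2 = res2.x, float(res2.fun)
            converged = bool(res2.success) or abs(res2.fun - res.fun) < 1e-4
    else:
        psi, converged = np.zeros(1), True
        neg2 = float(ws.neg2ll(psi))

    lam, phi = ws.unpack(psi)
    return _assemble(ws, lam, phi, neg2, converged, ndim)


def _assemble(ws, lam, phi, neg2, converged, ndim) -> MixedFitResult:
    n, p, q = ws.n, ws.p, ws.q
    guu, gzu, gzz, _ = ws.cross_at(phi)
    if q:
        pen = np.repeat(1.0 / lam, ws.qs)
        c = np.zeros((p + q, p + q))
        c[:p, :p] = guu[:p, :p]
        c[:p, p:] = gzu[:, :p].T
        c[p:, :p] = gzu[:, :p]
        c[p:, p:] = gzz + np.diag(pen)
        rhs = np.concatenate([guu[:p, p], gzu[:, p]])
        c0 = c.copy()
        c0[p:, p:] -= np.diag(pen)
        # profiled sigma^2 via the Woodbury-reduced GLS residual sum of squares
        cf = cho_factor(gzz + np.diag(pen), lower=True)
        g = guu - gzu.T @ cho_solve(cf, gzu)
    else:
        c = guu[:p, :p]
        rhs = guu[:p, p]
        c0 = c
        g = guu
    beta_gls = np.linalg.solve(g[:p, :p], g[:p, p])
    sigma2 = float(g[p, p] - g[:p, p] @ beta_gls) / n

    cinv = np.linalg.inv(c)
    theta = cinv @ rhs
    edf = (cinv * c0).sum(axis=1)

    variances = {b.name: float(l * sigma2) for b, l in zip(ws.blocks, lam)}
    slices = {"fixed": slice(0, p)}
    at = p
    for b in ws.blocks:
        slices[b.name] = slice(at, at + b.q)
        at += b.q
    return MixedFitResult(
        beta=theta[:p],
        b=theta[p:],
        cov=sigma2 * cinv,
        edf=edf,
        sigma2=sigma2,
        variances=variances,
        phi=float(phi),
        loglik=-0.5 * neg2,
        n=n,
        p=p,
        converged=converged,
        block_slices=slices,
        n_opt_params=ndim,
    )
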