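"""Penalized cubic spline bases (P-splines) for the additive model terms.

Each smooth is a cubic B-spline basis on equally spaced knots with a
second-order difference penalty. The basis is centered (sum-to-zero over the
training rows) so it is identifiable next to an intercept, and then rotated
into the penalty's eigenbasis, which splits it into

* a *null-space* column (the linear trend, unpenalized, treated as a fixed
  effect), and
* *range-space* columns whose coefficients are i.i.d. Gaussian under the
  mixed-model representation of the penalty — one variance parameter per
  smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

_DEGREE = 3
_NULL_TOL = 1e-8


def _knots(xmin: float, xmax: float, k: int) -> np.ndarray:
    if xmax <= xmin:
        xmax = xmin + 1.0
    spacing = (xmax - xmin) / (k - _DEGREE)
    return xmin + spacing * (np.arange(k + _DEGREE + 1) - _DEGREE)


def _raw_basis(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), t[_DEGREE], t[-_DEGREE - 1])
    # keep the right boundary inside the half-open support of the last spline
    x = np.minimum(x, np.nextafter(t[-_DEGREE - 1], -np.inf))
    return BSpline.design_matrix(x, t, _DEGREE).toarray()


@dataclass
class SmoothBasis:
    """A fitted smooth-term basis, reusable on new covariate values."""

    cov: str
    k: int = 8
    by: str | None = None
    by_level: object | None = None
    knots: np.ndarray = field(default=None, repr=False)
    center: np.ndarray = field(default=None, repr=False)
    to_null: np.ndarray = field(default=None, repr=False)
    to_range: np.ndarray = field(default=None, repr=False)

    def fit(self, x: np.ndarray) -> "SmoothBasis":
        x = np.asarray(x, dtype=float)
        self.knots = _knots(float(x.min()), float(x.max()), self.k)
        b = _raw_basis(x, self.knots)
        # sum-to-zero constraint over the training rows
        c = b.mean(axis=0)
        q, _ = np.linalg.qr(c[:, None], mode="complete")
        zc = q[:, 1:]  # k x (k-1)
        d2 = np.diff(np.eye(self.k), n=2, axis=0)
        s = zc.T @ (d2.T @ d2) @ zc
        eigval, eigvec = np.linalg.eigh(s)
        null = eigval < _NULL_TOL * eigval.max()
        if not null.any():  # numerical safety: force at least the smallest
            null = eigval == eigval.min()
        self.to_null = zc @ eigvec[:, null]
        rng_val, rng_vec = eigval[~null], eigvec[:, ~null]
        self.to_range = zc @ rng_vec / np.sqrt(rng_val)
        self.center = c
        return self

    @property
    def n_null(self) -> int:
        return self.to_null.shape[1]

    @property
    def n_range(self) -> int:
        return self.to_range.shape[1]

    def transform(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Null-space and range-space design columns at new covariate values."""
        b = _raw_basis(np.asarray(x, dtype=float), self.knots)
        return b @ self.to_null, b @ self.to_range
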