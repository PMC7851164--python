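"""Cubic regression spline basis with a second-derivative roughness penalty.

The basis is the cardinal natural-cubic-spline construction: with knots
``x*_1 < ... < x*_k`` placed at quantiles of the observed covariate, the
coefficients are the function values at the knots and evaluation interpolates
with a natural cubic spline (linear extrapolation beyond the boundary knots).
The penalty is the integrated squared second derivative, a banded quadratic
form in the knot values with null space = linear functions (rank k-2).

For use inside additive models the basis is centered: a sum-to-zero
constraint over the observed covariate values is absorbed by a rank-reducing
reparameterization, leaving k-1 identifiable columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve


def place_knots(x: np.ndarray, k: int) -> np.ndarray:
    """k knots at evenly spaced quantiles of the unique covariate values."""
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < k:
        raise ValueError(f"need at least {k} distinct covariate values, got {ux.size}")
    probs = np.linspace(0.0, 1.0, k)
    knots = np.quantile(ux, probs)
    # quantiles of few unique values can coincide; nudge to strict ordering
    if np.any(np.diff(knots) <= 0):
        knots = np.linspace(ux[0], ux[-1], k)
    return knots


def _cr_matrices(knots: np.ndarray):
    """Banded matrices of the natural-spline construction.

    Returns F (k-2, k) mapping knot values to interior second derivatives,
    and the penalty S = D' B^{-1} D (k, k) where D, B are the classical
    band matrices built from the knot spacings.
    """
    h = np.diff(knots)
    k = len(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    F = solve(B, D, assume_a="pos")
    S = D.T @ F
    S = (S + S.T) / 2.0
    return F, S


@dataclass
class SmoothBasis:
    """Centered cubic-regression-spline basis for one covariate.

    Attributes
    ----------
    knots : (k,) knot locations.
    penalty : (k-1, k-1) centered roughness penalty, PSD with a
        one-dimensional null space (the centered linear function).
    center_transform : (k, k-1) map from centered to uncentered coefficients.
    col_means : (k,) means of the uncentered basis over the observed values
        (the absorbed sum-to-zero constraint).
    """

    knots: np.ndarray
    penalty: np.ndarray
    center_transform: np.ndarray
    col_means: np.ndarray
    _F: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(self.knots)

    @property
    def n_coef(self) -> int:
        return self.k - 1

    def evaluate_raw(self, x: np.ndarray) -> np.ndarray:
        """Uncentered (k-column) basis rows at arbitrary covariate values."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        knots, F = self.knots, self._F
        k = len(knots)
        X = np.zeros((x.size, k))
        j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
        lo, hi = knots[j], knots[j + 1]
        h = hi - lo
        inside = (x >= knots[0]) & (x <= knots[-1])
        xm = np.clip(x, knots[0], knots[-1])
        ap = (xm - lo) / h
        am = (hi - xm) / h
        cm = ((hi - xm) ** 3 / h - h * (hi - xm)) / 6.0
        cp = ((xm - lo) ** 3 / h - h * (xm - lo)) / 6.0
        rows = np.arange(x.size)
        X[rows, j] += am
        X[rows, j + 1] += ap
        # curvature terms pull in all knot values through F
        gamma = np.zeros((k, k))
        gamma[1:-1] = F
        X += cm[:, None] * gamma[j] + cp[:, None] * gamma[j + 1]
        # linear extrapolation beyond the boundary using the boundary slope
        out_lo = x < knots[0]
        out_hi = x > knots[-1]
        if np.any(out_lo) or np.any(out_hi):
            eps = 1e-6 * (knots[-1] - knots[0])
            for out, x0 in ((out_lo, knots[0]), (out_hi, knots[-1])):
                if not np.any(out):
                    continue
                sign = -1.0 if x0 == knots[0] else 1.0
                b0 = self._interior_rows(np.array([x0]))
                b1 = self._interior_rows(np.array([x0 - sign * eps]))
                slope = sign * (b0 - b1) / eps
                X[out] = b0 + (x[out] - x0)[:, None] * slope
        _ = inside  # clipping already handled interior evaluation
        return X

    def _interior_rows(self, x: np.ndarray) -> np.ndarray:
        knots, F = self.knots, self._F
        k = len(knots)
        X = np.zeros((x.size, k))
        j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
        lo, hi = knots[j], knots[j + 1]
        h = hi - lo
        ap = (x - lo) / h
        am = (hi - x) / h
        cm = ((hi - x) ** 3 / h - h * (hi - x)) / 6.0
        cp = ((x - lo) ** 3 / h - h * (x - lo)) / 6.0
        rows = np.arange(x.size)
        X[rows, j] += am
        X[rows, j + 1] += ap
        gamma = np.zeros((k, k))
        gamma[1:-1] = F
        X += cm[:, None] * gamma[j] + cp[:, None] * gamma[j + 1]
        return X

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Centered (k-1 column) basis rows at arbitrary covariate values."""
        return (self.evaluate_raw(x) - self.col_means) @ self.center_transform


def build_basis(x: np.ndarray, k: int = 6) -> SmoothBasis:
    """Centered cubic-regression-spline basis from observed covariate values.

    ``k`` is the basis dimension before the sum-to-zero constraint; the
    returned basis has ``k - 1`` columns.
    """
    x = np.asarray(x, dtype=float)
    knots = place_knots(x, k)
    F, S_raw = _cr_matrices(knots)
    basis = SmoothBasis(
        knots=knots,
        penalty=np.empty(0),
        center_transform=np.empty(0),
        col_means=np.zeros(k),
        _F=F,
    )
    Xraw = basis.evaluate_raw(x)
    col_means = Xraw.mean(axis=0)
    # absorb the constraint c'beta = 0 (c = col means) via the QR null space
    c = col_means / np.linalg.norm(col_means)
    Q = np.linalg.qr(np.column_stack([c, np.eye(k)]), mode="complete")[0]
    Z = Q[:, 1:]  # (k, k-1), orthonormal complement of c
    basis.col_means = col_means
    basis.center_transform = Z
    Sc = Z.T @ S_raw @ Z
    basis.penalty = (Sc + Sc.T) / 2.0
    return basis
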