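"""Natural cubic spline basis for smooth temperature adjustment.

Construction follows the convention of R's ``splines::ns``: for ``df``
basis columns (no intercept) there are ``df - 1`` internal knots placed at
equally spaced quantiles of the data (df = 3 puts them at the 1/3 and 2/3
quantiles), with boundary knots at the data range.  A cubic B-spline basis
on those knots is projected onto the subspace whose second derivatives
vanish at both boundary knots, so every basis function continues linearly
beyond the boundaries; evaluation outside the boundary knots uses that
linear extension explicitly.

The projection uses a QR factorisation of the boundary-curvature
constraints, so individual columns are an orthogonal mix of any other
implementation's columns; the spanned function space — which is what the
regression sees — is identical.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["NaturalSplineBasis", "natural_spline_basis"]


class NaturalSplineBasis:
    """Natural cubic spline design matrix with ``df`` columns.

    Parameters
    ----------
    x : array-like
        Values the basis is anchored to (knot quantiles, boundary range).
    df : int
        Number of basis columns (default 3).
    internal_knots, boundary_knots : array-like, optional
        Explicit knot locations; by default internal knots sit at the
        ``k/df`` quantiles (k = 1..df-1) and boundaries at min/max of *x*.
    """

    def __init__(self, x, df: int = 3, internal_knots=None, boundary_knots=None):
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if df < 1:
            raise ValueError("df must be >= 1")
        if np.unique(x).size < df + 1:
            raise ValueError(f"need at least {df + 1} distinct values for a df={df} basis")
        if boundary_knots is None:
            boundary_knots = (float(x.min()), float(x.max()))
        b_lo, b_hi = (float(b) for b in boundary_knots)
        if not b_lo < b_hi:
            raise ValueError("degenerate boundary knots")
        if internal_knots is None:
            n_internal = df - 1
            probs = np.linspace(0.0, 1.0, n_internal + 2)[1:-1]
            inside = x[(x >= b_lo) & (x <= b_hi)]
            internal_knots = np.quantile(inside, probs) if n_internal else np.empty(0)
        internal_knots = np.sort(np.asarray(internal_knots, dtype=float))

        self.df = int(df)
        self.internal_knots = internal_knots
        self.boundary_knots = (b_lo, b_hi)
        # full knot vector: boundary knots with multiplicity 4 (cubic order)
        self._aknots = np.sort(np.concatenate([[b_lo] * 4, internal_knots, [b_hi] * 4]))
        m = internal_knots.size + 4  # raw cubic B-spline columns

        # curvature of each B-spline at the two boundary knots; drop the
        # intercept column, then project onto the null space of the constraints
        const = np.vstack(
            [self._raw_design(np.array([b_lo, b_hi]), derivative=2)]
        )  # (2, m)
        const = const[:, 1:]
        q_full, _ = np.linalg.qr(const.T, mode="complete")  # (m-1, m-1)
        self._project = q_full[:, 2:]  # (m-1, df)
        if self._project.shape[1] != self.df:
            raise RuntimeError("internal knot bookkeeping error")
        self._x = x
        self.matrix = self.design(x)

    # -- raw (unconstrained) cubic B-spline design ---------------------------
    def _raw_design(self, pts: np.ndarray, derivative: int = 0) -> np.ndarray:
        t = self._aknots
        m = t.size - 4
        if derivative == 0:
            return BSpline.design_matrix(pts, t, 3, extrapolate=True).toarray()
        out = np.empty((pts.size, m))
        for j in range(m):
            c = np.zeros(m)
            c[j] = 1.0
            out[:, j] = BSpline(t, c, 3, extrapolate=True).derivative(derivative)(pts)
        return out

    def design(self, x) -> np.ndarray:
        """Evaluate the df basis columns at new points.

        Points beyond the boundary knots follow the linear (first-order
        Taylor) extension at the nearer boundary — the defining property of a
        natural spline.
        """
        x = np.asarray(x, dtype=float)
        flat = x.ravel()
        b_lo, b_hi = self.boundary_knots
        raw = np.zeros((flat.size, self._aknots.size - 4))
        inside = (flat >= b_lo) & (flat <= b_hi)
        if inside.any():
            raw[inside] = self._raw_design(flat[inside])
        for is_low, pivot in ((True, b_lo), (False, b_hi)):
            mask = (flat < b_lo) if is_low else (flat > b_hi)
            if mask.any():
                val = self._raw_design(np.array([pivot]))
                der = self._raw_design(np.array([pivot]), derivative=1)
                raw[mask] = val + (flat[mask] - pivot)[:, None] * der
        basis = raw[:, 1:] @ self._project
        nan = ~np.isfinite(flat)
        if nan.any():
            basis[nan] = np.nan
        return basis.reshape(*x.shape, self.df)


def natural_spline_basis(x, df: int = 3, **kwargs) -> NaturalSplineBasis:
    """Build a natural cubic spline basis (see :class:`NaturalSplineBasis`)."""
    return NaturalSplineBasis(x, df=df, **kwargs)
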