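"""B-spline knot sequences, basis evaluation, and basis derivatives.

The monotone output layer builds a strictly increasing function from a
degree-``p`` B-spline basis ``B_1,...,B_{L+p}`` on an ascending knot
sequence with ``L`` interior segments covering ``[0, t_max]``.  Everything
downstream (survival curves, likelihood terms, roughness penalties) reduces
to evaluating this basis and its derivatives, so the contract here is kept
deliberately small: dense vectors of length ``L + p``, vectorised over the
evaluation points.

Evaluation is delegated to :class:`scipy.interpolate.BSpline` design
matrices; derivatives use the standard knot-difference recursion that lowers
the degree by one per order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "KnotSequence",
    "build_knots",
    "evaluate_basis",
    "basis_derivative",
    "basis_matrix",
    "greville_abscissae",
    "second_derivative_gram",
]


@dataclass(frozen=True)
class KnotSequence:
    """Ascending knot vector for a degree-``p`` basis with ``L`` segments.

    The knots satisfy ``knots[p] = 0`` and ``knots[L + p] = t_max`` (0-based),
    so the basis spans the follow-up window ``[0, t_max]`` and the ``p``
    exterior knots on each side keep every basis function well defined at the
    domain ends.
    """

    L: int
    p: int
    t_max: float
    knots: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        object.__setattr__(self, "knots", knots)
        if len(knots) != self.L + 2 * self.p + 1:
            raise ValueError(
                f"knot vector must have length L + 2p + 1 = "
                f"{self.L + 2 * self.p + 1}, got {len(knots)}"
            )
        if np.any(np.diff(knots) < 0):
            raise ValueError("knots must be nondecreasing")
        if abs(knots[self.p]) > 1e-12 or abs(knots[self.L + self.p] - self.t_max) > 1e-12:
            raise ValueError("knots[p] must be 0 and knots[L+p] must be t_max")

    @property
    def n_basis(self) -> int:
        """Number of basis functions, ``L + p``."""
        return self.L + self.p

    def to_dict(self) -> dict:
        return {"L": self.L, "p": self.p, "t_max": self.t_max}

    @classmethod
    def from_dict(cls, d: dict) -> "KnotSequence":
        return build_knots(int(d["L"]), int(d["p"]), float(d["t_max"]))


def build_knots(L: int, p: int, t_max: float) -> KnotSequence:
    """Evenly spaced knot sequence ``xi_j = (j - p - 1) * t_max / L``.

    Parameters
    ----------
    L : int
        Number of interior segments, at least 1.
    p : int
        Spline degree, at least 2 (monotonicity of the output layer and the
        curvature penalty both need second derivatives).
    t_max : float
        Upper end of the follow-up window, strictly positive.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if p < 2:
        raise ValueError(f"p must be >= 2, got {p}")
    if not t_max > 0:
        raise ValueError(f"t_max must be positive, got {t_max}")
    j = np.arange(1, L + 2 * p + 2, dtype=float)
    knots = (j - p - 1) * (t_max / L)
    return KnotSequence(L=L, p=p, t_max=t_max, knots=knots)


def _check_domain(u: np.ndarray, ks: KnotSequence) -> np.ndarray:
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any(u < -1e-12) or np.any(u > ks.t_max + 1e-12):
        raise ValueError(
            f"evaluation points must lie in [0, {ks.t_max}], "
            f"got range [{u.min()}, {u.max()}]"
        )
    # clip roundoff at the ends; the last interval is treated as closed so the
    # basis is defined on the full [0, t_max]
    return np.clip(u, 0.0, ks.t_max)


def basis_matrix(u, ks: KnotSequence, order: int = 0) -> np.ndarray:
    """Dense matrix of basis values (or ``order``-th derivatives).

    Returns an array of shape ``(len(u), L + p)``.  ``order = 0`` gives the
    basis itself; ``order >= 1`` applies the derivative recursion
    ``B'_{l,p} = p/(xi_{l+p}-xi_l) B_{l,p-1} - p/(xi_{l+p+1}-xi_{l+1}) B_{l+1,p-1}``
    repeatedly.  Orders beyond ``p`` are identically zero because each piece
    is a degree-``p`` polynomial.
    """
    u = _check_domain(u, ks)
    if order < 0:
        raise ValueError("order must be >= 0")
    K = ks.n_basis
    if order > ks.p:
        return np.zeros((len(u), K))

    # Coefficient matrix C maps lower-degree basis values to the requested
    # derivatives of the original degree-p basis: rows index the original
    # basis functions, columns the degree-(p-order) ones, all sharing the
    # full knot vector.
    knots = ks.knots
    deg = ks.p
    C = np.eye(K)
    for _ in range(order):
        # d/du B_{l,deg} = deg/(t_{l+deg}-t_l) B_{l,deg-1}
        #                - deg/(t_{l+deg+1}-t_{l+1}) B_{l+1,deg-1}
        D = np.zeros((C.shape[1], C.shape[1] + 1))
        for l in range(C.shape[1]):
            denom1 = knots[l + deg] - knots[l]
            denom2 = knots[l + deg + 1] - knots[l + 1]
            if denom1 > 0:
                D[l, l] += deg / denom1
            if denom2 > 0:
                D[l, l + 1] -= deg / denom2
        C = C @ D
        deg -= 1

    lo = BSpline.design_matrix(u, knots, deg, extrapolate=False).toarray()
    return lo @ C.T


def evaluate_basis(u, ks: KnotSequence) -> np.ndarray:
    """Basis values ``(B_1(u), ..., B_{L+p}(u))``.

    Scalars return a 1-D vector of length ``L + p``; arrays return a matrix
    with one row per evaluation point.  On ``[0, t_max]`` the values are
    nonnegative, sum to one, and at most ``p + 1`` of them are nonzero.
    """
    scalar = np.isscalar(u) or np.ndim(u) == 0
    out = basis_matrix(u, ks, order=0)
    return out[0] if scalar else out


def basis_derivative(u, ks: KnotSequence, order: int = 1) -> np.ndarray:
    """``order``-th derivatives of each basis function at ``u``.

    Orders exceeding the degree return all zeros (the piecewise polynomial is
    exhausted) rather than raising.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    scalar = np.isscalar(u) or np.ndim(u) == 0
    out = basis_matrix(u, ks, order=order)
    return out[0] if scalar else out


def greville_abscissae(ks: KnotSequence) -> np.ndarray:
    """Knot averages ``(xi_{l+1} + ... + xi_{l+p}) / p`` for each basis.

    A spline whose coefficients are affine in these abscissae reproduces the
    corresponding affine function of time; used to verify that the curvature
    penalty vanishes for linear output.
    """
    knots = ks.knots
    return np.array(
        [knots[l + 1 : l + ks.p + 1].mean() for l in range(ks.n_basis)]
    )


def second_derivative_gram(ks: KnotSequence) -> np.ndarray:
    """Gram matrix ``M[l, m] = int_0^{t_max} B''_l(u) B''_m(u) du``.

    Computed exactly with per-interval Gauss-Legendre quadrature using
    ``p - 1`` nodes: the integrand is piecewise polynomial of degree
    ``2(p - 2)``, which ``p - 1`` nodes integrate without error.  The
    roughness penalty of a spline with coefficient vector ``c`` is then the
    quadratic form ``c @ M @ c``.
    """
    nodes, weights = np.polynomial.legendre.leggauss(max(ks.p - 1, 1))
    edges = np.linspace(0.0, ks.t_max, ks.L + 1)
    M = np.zeros((ks.n_basis, ks.n_basis))
    for a, b in zip(edges[:-1], edges[1:]):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        u = mid + half * nodes
        B2 = basis_matrix(u, ks, order=2)
        M += half * (B2.T * weights) @ B2
    return M
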