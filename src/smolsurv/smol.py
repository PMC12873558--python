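"""The smooth monotone output layer (SMOL).

A backbone network emits a real vector ``o`` of length ``L + p``.  The
positivity map ``phi`` leaves the first entry untouched and forces the rest
strictly positive; cumulative sums of ``phi(o)`` then serve as B-spline
coefficients, so the resulting spline

    O(u) = sum_l [ sum_{k<=l} phi(o_k) ] B_l(u)

has strictly increasing coefficients and is therefore strictly increasing in
``u`` on ``[0, t_max]`` for any degree ``p >= 2``.  Conditional survival is
the exponentiated difference ``S(s | t) = exp(O(t) - O(s))``, which lies in
``(0, 1]``, equals one at ``s = t``, and decreases strictly in ``s`` —
without forcing the curve to reach zero at ``t_max``.

All functions accept a single output vector ``o`` of shape ``(L + p,)`` or a
batch ``(n, L + p)``, and scalar or vector evaluation points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bspline import KnotSequence, basis_matrix, build_knots

__all__ = [
    "SmolHead",
    "phi",
    "smol_output",
    "smol_derivative",
    "survival",
    "cumulative_incidence",
    "log_density",
]


@dataclass(frozen=True)
class SmolHead:
    """Knot sequence plus the positivity shift ``eps_phi`` (default 1e-8)."""

    ks: KnotSequence
    eps_phi: float = 1e-8

    def __post_init__(self) -> None:
        if not self.eps_phi > 0:
            raise ValueError("eps_phi must be positive")

    @classmethod
    def create(cls, L: int, p: int, t_max: float, eps_phi: float = 1e-8) -> "SmolHead":
        return cls(ks=build_knots(L, p, t_max), eps_phi=eps_phi)

    @property
    def n_basis(self) -> int:
        return self.ks.n_basis


def _check_o(o, head: SmolHead) -> np.ndarray:
    o = np.asarray(o, dtype=float)
    if o.shape[-1] != head.n_basis:
        raise ValueError(
            f"output vector must have length L + p = {head.n_basis}, "
            f"got {o.shape[-1]}"
        )
    return o


def phi(o, eps_phi: float = 1e-8, head: SmolHead | None = None) -> np.ndarray:
    """Shifted rectified linear map enforcing positivity beyond entry one.

    Entry 1 passes through unchanged; entries ``2..L+p`` become
    ``max(0, o_l) + eps_phi`` and are therefore strictly positive.
    """
    if head is not None:
        o = _check_o(o, head)
        eps_phi = head.eps_phi
    o = np.asarray(o, dtype=float)
    out = np.maximum(o, 0.0) + eps_phi
    out[..., 0] = o[..., 0]
    return out


def _coefficients(o, head: SmolHead) -> np.ndarray:
    """Strictly increasing spline coefficients: cumulative sums of phi(o)."""
    return np.cumsum(phi(_check_o(o, head), head.eps_phi), axis=-1)


def smol_output(u, o, head: SmolHead) -> np.ndarray:
    """Value of the monotone spline at ``u``.

    Broadcasting: with ``o`` of shape ``(n, K)`` and ``u`` of shape ``(m,)``
    the result is ``(n, m)``; scalar/1-D inputs collapse accordingly.
    """
    c = _coefficients(o, head)
    B = basis_matrix(u, head.ks, order=0)  # (m, K)
    val = c @ B.T
    if np.isscalar(u) or np.ndim(u) == 0:
        val = val[..., 0]
    return val if val.ndim else float(val)


def smol_derivative(u, o, head: SmolHead, order: int = 1) -> np.ndarray:
    """``order``-th derivative (order 1 or 2) of the monotone spline at ``u``.

    The first derivative is strictly positive everywhere on the domain.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    # suffix-sum form: O^(r)(u) = sum_k phi_k * sum_{l >= k} B^(r)_l(u).
    # For order 1 every term with k >= 2 is nonnegative and the k = 1 term
    # vanishes (the basis derivatives sum to zero), so the sum is free of the
    # cancellation the cumulative-coefficient form suffers when the
    # derivative sits near the eps_phi floor.
    ph = phi(_check_o(o, head), head.eps_phi)
    B = basis_matrix(u, head.ks, order=order)
    suffix = np.flip(np.cumsum(np.flip(B, -1), -1), -1)
    val = ph @ suffix.T
    if np.isscalar(u) or np.ndim(u) == 0:
        val = val[..., 0]
    return val if val.ndim else float(val)


def _check_interval(s, t, head: SmolHead):
    s_arr = np.asarray(s, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(s_arr < t_arr - 1e-12):
        raise ValueError("evaluation time s must satisfy s >= t")
    if np.any(t_arr < -1e-12) or np.any(s_arr > head.ks.t_max + 1e-12):
        raise ValueError(f"times must lie within [0, {head.ks.t_max}]")


def survival(s, t, o_t, head: SmolHead) -> np.ndarray:
    """Conditional survival ``S(s | t) = exp(O(t) - O(s))``.

    ``o_t`` is the backbone output conditioned on the history up to ``t``.
    The value is 1 at ``s = t`` and lies in the open interval (0, 1) for
    ``s > t``; the difference is formed in log space before a single
    exponentiation, so large spline values cannot overflow.
    """
    _check_interval(s, t, head)
    log_s = smol_output(t, o_t, head) - smol_output(s, o_t, head)
    return np.exp(np.minimum(log_s, 0.0))


def cumulative_incidence(s, t, o_t, head: SmolHead) -> np.ndarray:
    """Conditional cumulative incidence ``F(s | t) = 1 - S(s | t)``."""
    return 1.0 - survival(s, t, o_t, head)


def log_density(s, t, o_t, head: SmolHead) -> np.ndarray:
    """Log of ``dF(s | t)/ds``: ``log S(s | t) + log O'(s)``.

    Finite for every admissible ``s`` because the spline derivative is
    strictly positive.
    """
    _check_interval(s, t, head)
    log_s = np.minimum(smol_output(t, o_t, head) - smol_output(s, o_t, head), 0.0)
    return log_s + np.log(smol_derivative(s, o_t, head, order=1))
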