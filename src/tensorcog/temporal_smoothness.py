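"""Generalized temporal smoothness operator for the weight trajectory.

The weight matrices W_1..W_t over consecutive prediction time points are
unfolded column-wise into W_f of shape (d1*d2, t). The plain first-difference
matrix H maps W_f to the per-step changes delta_w_i = w_i - w_{i+1}. The
generalized prior blends each step with all preceding ones through mixing
parameters alpha_i in [0, 1]:

    Delta_w_1 = delta_w_1
    Delta_w_i = alpha_{i-1} * Delta_w_{i-1} + (1 - alpha_{i-1}) * delta_w_i

which in matrix form is P(alpha) = H D_1(alpha_1) ... D_{t-2}(alpha_{t-2});
the penalty is ||W_f P(alpha)||_F^2. With all alphas zero P reduces to H
(pure adjacent-step smoothness). For t = 2 there are no mixing parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SmoothnessOperator", "build_H", "build_D", "build_P", "smoothness_penalty"]


def build_H(t: int) -> np.ndarray:
    """t x (t-1) first-difference matrix: (W H)[:, j] = w_j - w_{j+1}."""
    if t < 2:
        raise ValueError("need at least 2 time points")
    H = np.zeros((t, t - 1))
    idx = np.arange(t - 1)
    H[idx, idx] = 1.0
    H[idx + 1, idx] = -1.0
    return H


def build_D(t: int, i: int, alpha: float) -> np.ndarray:
    """(t-1) x (t-1) blending factor D_i: identity except
    D_i[i-1, i] = alpha and D_i[i, i] = 1 - alpha (1-based i in 1..t-2)."""
    if not 1 <= i <= t - 2:
        raise ValueError(f"i must be in [1, {t - 2}], got {i}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    D = np.eye(t - 1)
    D[i - 1, i] = alpha
    D[i, i] = 1.0 - alpha
    return D


@dataclass(frozen=True)
class SmoothnessOperator:
    """Holds H, the D_i factors, and their product P = H D_1 ... D_{t-2}."""

    t: int
    alphas: tuple[float, ...]
    H: np.ndarray = field(repr=False)
    D_list: tuple[np.ndarray, ...] = field(repr=False)
    P: np.ndarray = field(repr=False)

    @property
    def PPt(self) -> np.ndarray:
        """P P^T, the t x t Gram matrix entering the penalty gradient."""
        return self.P @ self.P.T


def build_P(t: int, alphas=()) -> SmoothnessOperator:
    """Assemble the generalized smoothness operator for t time points."""
    alphas = tuple(float(a) for a in np.atleast_1d(np.asarray(alphas, dtype=float))) if len(
        np.atleast_1d(alphas)
    ) else ()
    if len(alphas) != max(t - 2, 0):
        raise ValueError(f"expected {max(t - 2, 0)} alphas for t={t}, got {len(alphas)}")
    H = build_H(t)
    D_list = tuple(build_D(t, i, a) for i, a in enumerate(alphas, start=1))
    P = H.copy()
    for D in D_list:
        P = P @ D
    return SmoothnessOperator(t=t, alphas=alphas, H=H, D_list=D_list, P=P)


def smoothness_penalty(W_f: np.ndarray, op: SmoothnessOperator) -> float:
    """Squared Frobenius norm ||W_f P(alpha)||_F^2."""
    W_f = np.asarray(W_f, dtype=float)
    if W_f.ndim != 2 or W_f.shape[1] != op.t:
        raise ValueError(f"W_f must be (features, {op.t}), got {W_f.shape}")
    return float(np.sum((W_f @ op.P) ** 2))
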