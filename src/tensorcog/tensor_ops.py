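"""Dense third-order tensor primitives: unfolding, CP reconstruction and ALS.

Conventions follow the standard Kolda–Bader matricization: the mode-``m``
unfolding of a ``d1 x d2 x d3`` tensor has the remaining modes ordered so that
``unfold(T, 0) == A @ khatri_rao(C, B).T`` for ``T = cp_reconstruct(A, B, C)``.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import khatri_rao

__all__ = [
    "unfold",
    "cp_reconstruct",
    "cp_als",
    "normalize_cp_factors",
    "power_iteration_norm",
]


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` matricization of a 3-way tensor (mode in {0, 1, 2})."""
    if tensor.ndim != 3:
        raise ValueError(f"expected a 3-way tensor, got ndim={tensor.ndim}")
    if mode == 0:
        return tensor.transpose(0, 2, 1).reshape(tensor.shape[0], -1)
    if mode == 1:
        return tensor.transpose(1, 2, 0).reshape(tensor.shape[1], -1)
    if mode == 2:
        return tensor.transpose(2, 1, 0).reshape(tensor.shape[2], -1)
    raise ValueError(f"mode must be 0, 1 or 2, got {mode}")


def cp_reconstruct(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Reconstruct the rank-r CP tensor ``sum_q a_q o b_q o c_q``.

    Entry ``(i, j, k)`` equals ``sum_q A[i, q] * B[j, q] * C[k, q]``.
    """
    if not (A.ndim == B.ndim == C.ndim == 2):
        raise ValueError("CP factors must be matrices")
    if not (A.shape[1] == B.shape[1] == C.shape[1]):
        raise ValueError(
            f"rank mismatch across CP factors: {A.shape[1]}, {B.shape[1]}, {C.shape[1]}"
        )
    return np.einsum("iq,jq,kq->ijk", A, B, C, optimize=True)


def normalize_cp_factors(
    A: np.ndarray, B: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rescale factors so A and B have unit-norm, sign-fixed columns.

    Column norms and signs are absorbed into C; the largest-magnitude entry of
    each A/B column is made positive. This removes the scale and sign
    indeterminacy of the CP so that ``A @ B.T`` is well defined across fits
    (component permutation does not affect ``A @ B.T`` as a sum).
    """
    A, B, C = A.copy(), B.copy(), C.copy()
    for fac in (A, B):
        norms = np.linalg.norm(fac, axis=0)
        norms[norms == 0] = 1.0
        signs = np.sign(fac[np.abs(fac).argmax(axis=0), np.arange(fac.shape[1])])
        signs[signs == 0] = 1.0
        fac /= norms * signs
        C *= norms * signs
    return A, B, C


def cp_als(
    tensor: np.ndarray,
    rank: int,
    *,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int | np.random.Generator = 0,
    ridge: float = 1e-12,
    n_starts: int = 8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Unregularized CP decomposition by alternating least squares.

    ALS on real data tensors can stall in local optima, so ``n_starts``
    random initializations are run and the lowest-error one kept; this makes
    the returned factors reproducible across seeds whenever the best basin
    is reliably found.

    Parameters
    ----------
    tensor : (d1, d2, d3) array
    rank : number of rank-one components
    tol : stop when the relative change of the fit residual drops below this
    ridge : tiny Tikhonov term on the r x r normal equations for stability

    Returns
    -------
    (A, B, C, errors) with unit-norm sign-fixed A, B columns and the relative
    reconstruction error after each sweep of the winning start.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_starts):
            sub = rng.spawn(1)[0]
            cand = cp_als(tensor, rank, max_iter=max_iter, tol=tol, seed=sub,
                          ridge=ridge, n_starts=1)
            if best is None or cand[3][-1] < best[3][-1]:
                best = cand
        return best
    rng = np.random.default_rng(seed)
    d1, d2, d3 = tensor.shape
    A = rng.standard_normal((d1, rank))
    B = rng.standard_normal((d2, rank))
    C = rng.standard_normal((d3, rank))
    unf = [unfold(tensor, m) for m in range(3)]
    norm_x = np.linalg.norm(tensor)
    if norm_x == 0:
        zero = [np.zeros_like(f) for f in (A, B, C)]
        return zero[0], zero[1], zero[2], [0.0]

    errors: list[float] = []
    eye = np.eye(rank)
    def _solve(mode: int, f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
        gram = (f1.T @ f1) * (f2.T @ f2)
        mttkrp = unf[mode] @ khatri_rao(f1, f2)
        return np.linalg.solve(gram + ridge * eye, mttkrp.T).T

    for _ in range(max_iter):
        A = _solve(0, C, B)
        B = _solve(1, C, A)
        C = _solve(2, B, A)
        err = np.linalg.norm(tensor - cp_reconstruct(A, B, C)) / norm_x
        errors.append(err)
        if len(errors) > 1 and abs(errors[-2] - errors[-1]) < tol * max(errors[-2], 1e-300):
            break
    A, B, C = normalize_cp_factors(A, B, C)
    return A, B, C, errors


def power_iteration_norm(
    matvec,
    dim: int,
    *,
    n_iter: int = 50,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-7,
) -> float:
    """Largest eigenvalue of a symmetric PSD operator given as a matvec.

    Used to estimate the Lipschitz constant of block-quadratic terms without
    forming their Hessians.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(dim)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = matvec(v)
        lam_new = float(v @ w)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
        if abs(lam_new - lam) < tol * max(abs(lam_new), 1.0):
            lam = lam_new
            break
        lam = lam_new
    return max(lam, 0.0)
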