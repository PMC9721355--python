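"""Tensor multi-task regression with CP latent factors.

One prediction task per (patient, time point). The input is a single
similarity tensor X (d x d x n, symmetric zero-diagonal slices); the targets
Y (n x t) are cognitive scores at t future time points. Per time point the
model couples

* an empirical squared loss on the score prediction
  ``y_hat_n = sum_ij [(A_t B_t^T) * K * W_t * X_n]_ij`` (elementwise
  products, K the strictly upper-triangular duplicate-correction mask),
* a CP-factorization fit ``(lam/2) ||X - [[A_t, B_t, C_t]]||_F^2`` that
  anchors the latent biomarker factors A_t, B_t (and sample factors C_t)
  to the tensor,
* an l1 penalty ``beta (||W_t||_1 + ||A_t||_1 + ||B_t||_1 + ||C_t||_1)``,

and across time points a generalized temporal smoothness penalty
``theta ||W_f P(alpha)||_F^2`` on the unfolded weight stack.

The joint objective is minimized by block proximal gradient descent
(blocks A_t -> B_t -> C_t per time point, then the W stack jointly for the
smoothness coupling), each block taking one soft-thresholded gradient step
with a backtracked step size, which makes the outer objective trace
monotonically non-increasing. C_t enters only the CP term, so prediction
for unseen patients needs only A_t, B_t, W_t and the new tensor slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .similarity_tensor import SimilarityTensor, correction_mask
from .temporal_smoothness import SmoothnessOperator, build_P, smoothness_penalty
from .tensor_ops import cp_als, cp_reconstruct, power_iteration_norm, unfold
from scipy.linalg import khatri_rao

__all__ = [
    "TMTLHyperparameters",
    "TMTLModel",
    "soft_threshold",
    "predict_sample",
    "objective_single",
    "objective_joint",
    "fit",
    "predict",
]

_MAX_BACKTRACKS = 60


@dataclass(frozen=True)
class TMTLHyperparameters:
    """Regularization weights and solver settings.

    lam : weight of the CP-factorization fit term (>= 0)
    beta : shared l1 weight on W_t, A_t, B_t, C_t (>= 0)
    theta : weight of the temporal smoothness penalty (>= 0)
    rank : number of CP latent factors r (1 <= r <= min(d1, d2))
    alphas : smoothness mixing parameters, length t-2 (None -> all zero)
    shared_factors : tie A/B/C across time points (ablation mode)
    init_sweeps : unregularized ALS sweeps used to warm-start the factors
    """

    lam: float = 1.0
    beta: float = 1e-3
    theta: float = 1e-3
    rank: int = 3
    alphas: tuple | None = None
    max_iter: int = 500
    tol: float = 1e-5
    seed: int = 0
    shared_factors: bool = False
    init_sweeps: int = 10

    def __post_init__(self) -> None:
        if min(self.lam, self.beta, self.theta) < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.max_iter < 0 or self.tol < 0:
            raise ValueError("max_iter and tol must be non-negative")


@dataclass
class TMTLModel:
    """Fitted per-time-point factors and weights."""

    A: list  # t matrices (d1, r)
    B: list  # t matrices (d2, r)
    C: list  # t matrices (n, r)
    W: list  # t matrices (d1, d2)
    K: np.ndarray
    hp: TMTLHyperparameters
    smoothness: SmoothnessOperator | None  # None for a single time point
    objective_trace: list = field(default_factory=list)
    fitted: bool = False
    biomarker_names: tuple | None = None

    @property
    def t(self) -> int:
        return len(self.W)

    @property
    def W_stack(self) -> np.ndarray:
        """(d1, d2, t) weight tensor."""
        return np.stack(self.W, axis=-1)

    def W_unfolded(self) -> np.ndarray:
        """(d1*d2, t) column-wise unfolding used by the smoothness penalty."""
        return np.stack([w.ravel() for w in self.W], axis=1)

    def save(self, path) -> None:
        arrays = {"K": self.K, "trace": np.asarray(self.objective_trace)}
        for i in range(self.t):
            arrays |= {f"A{i}": self.A[i], f"B{i}": self.B[i],
                       f"C{i}": self.C[i], f"W{i}": self.W[i]}
        hp = self.hp
        arrays["hp"] = np.array([hp.lam, hp.beta, hp.theta, hp.rank, hp.max_iter,
                                 hp.tol, hp.seed, int(hp.shared_factors), hp.init_sweeps])
        arrays["alphas"] = np.asarray(self.smoothness.alphas, dtype=float)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "TMTLModel":
        z = np.load(path)
        t = sum(1 for k in z.files if k.startswith("W"))
        v = z["hp"]
        hp = TMTLHyperparameters(lam=v[0], beta=v[1], theta=v[2], rank=int(v[3]),
                                 alphas=tuple(z["alphas"]), max_iter=int(v[4]), tol=v[5],
                                 seed=int(v[6]), shared_factors=bool(v[7]), init_sweeps=int(v[8]))
        op = build_P(t, tuple(z["alphas"])) if t >= 2 else None
        return cls(A=[z[f"A{i}"] for i in range(t)], B=[z[f"B{i}"] for i in range(t)],
                   C=[z[f"C{i}"] for i in range(t)], W=[z[f"W{i}"] for i in range(t)],
                   K=z["K"], hp=hp, smoothness=op,
                   objective_trace=list(z["trace"]), fitted=True)


# ---------------------------------------------------------------------------
# elementary operations


def soft_threshold(Z: np.ndarray, tau: float) -> np.ndarray:
    """Entrywise l1 proximal map sign(z) * max(|z| - tau, 0)."""
    if tau < 0:
        raise ValueError("threshold must be non-negative")
    Z = np.asarray(Z, dtype=float)
    return np.sign(Z) * np.maximum(np.abs(Z) - tau, 0.0)


def predict_sample(A: np.ndarray, B: np.ndarray, W: np.ndarray, K: np.ndarray,
                   X_n: np.ndarray) -> float:
    """Score prediction for one patient slice: sum of (A B^T) * K * W * X_n."""
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must share the latent rank")
    if W.shape != X_n.shape or K.shape != X_n.shape or A.shape[0] != X_n.shape[0] \
            or B.shape[0] != X_n.shape[1]:
        raise ValueError("inconsistent shapes in prediction")
    return float(((A @ B.T) * K * W * X_n).sum())


def _l1(*mats: np.ndarray) -> float:
    return float(sum(np.abs(m).sum() for m in mats))


def _as_array(X) -> np.ndarray:
    return X.values if isinstance(X, SimilarityTensor) else np.asarray(X, dtype=float)


def objective_single(X, y_t: np.ndarray, A, B, C, W, hp: TMTLHyperparameters,
                     K: np.ndarray | None = None) -> float:
    """Per-time-point loss: empirical + CP fit + l1 (missing targets skipped)."""
    Xarr = _as_array(X)
    if K is None:
        K = correction_mask(Xarr.shape[0], Xarr.shape[1])
    coeff = ((A @ B.T) * K * W).ravel()
    yhat = Xarr.transpose(2, 0, 1).reshape(Xarr.shape[2], -1) @ coeff
    obs = ~np.isnan(y_t)
    emp = 0.5 * float(np.sum((yhat[obs] - y_t[obs]) ** 2))
    cp = 0.5 * hp.lam * float(np.sum((Xarr - cp_reconstruct(A, B, C)) ** 2))
    return emp + cp + hp.beta * _l1(W, A, B, C)


def objective_joint(X, Y: np.ndarray, model: TMTLModel, hp: TMTLHyperparameters | None = None,
                    smoothness_op: SmoothnessOperator | None = None) -> float:
    """Joint loss: sum of per-time-point losses plus the smoothness penalty."""
    hp = hp or model.hp
    op = smoothness_op if smoothness_op is not None else model.smoothness
    total = sum(
        objective_single(X, Y[:, ti], model.A[ti], model.B[ti], model.C[ti],
                         model.W[ti], hp, model.K)
        for ti in range(model.t)
    )
    if op is not None:
        total += hp.theta * smoothness_penalty(model.W_unfolded(), op)
    return total


# ---------------------------------------------------------------------------
# solver


class _FitState:
    """Precomputed views of the training problem shared across blocks."""

    def __init__(self, Xarr: np.ndarray, Y: np.ndarray, hp: TMTLHyperparameters):
        self.X = Xarr
        d1, d2, self.n = Xarr.shape
        self.n_targets, self.t = Y.shape
        self.Xmat = Xarr.transpose(2, 0, 1).reshape(self.n, d1 * d2)
        self.unf = [unfold(Xarr, m) for m in range(3)]
        self.obs = ~np.isnan(Y)
        self.Y0 = np.nan_to_num(Y, nan=0.0)
        self.K = correction_mask(d1, d2)
        self.hp = hp
        self.step: dict = {}

    def emp_loss(self, ti: int, A, B, W) -> tuple[float, np.ndarray]:
        """(loss, masked residual) of the empirical term at time point ti."""
        coeff = ((A @ B.T) * self.K * W).ravel()
        resid = (self.Xmat @ coeff - self.Y0[:, ti]) * self.obs[:, ti]
        return 0.5 * float(resid @ resid), resid

    def cp_loss(self, A, B, C) -> float:
        return 0.5 * self.hp.lam * float(np.sum((self.X - cp_reconstruct(A, B, C)) ** 2))


def _prox_step(state: _FitState, key, Z: np.ndarray, grad: np.ndarray,
               f_smooth, beta: float) -> np.ndarray:
    """One backtracked proximal gradient step on block ``Z``.

    Accepts the step when the smooth part satisfies the quadratic
    majorization bound, which guarantees the block objective (smooth + l1)
    does not increase.
    """
    eta = state.step.get(key, 1.0) * 1.5
    f0 = f_smooth(Z)
    for _ in range(_MAX_BACKTRACKS):
        Z_new = soft_threshold(Z - eta * grad, eta * beta)
        diff = Z_new - Z
        sq = float(np.sum(diff * diff))
        if sq == 0.0:
            break
        if f_smooth(Z_new) <= f0 + float(np.sum(grad * diff)) + sq / (2 * eta) + 1e-12:
            break
        eta *= 0.5
    state.step[key] = eta
    return Z_new


def _factor_grads(state: _FitState, ti: int, A, B, C, W):
    """Smooth-part gradients for the A and B blocks at time point ti."""
    lam = state.hp.lam
    _, resid = state.emp_loss(ti, A, B, W)
    R = (state.Xmat.T @ resid).reshape(state.X.shape[0], state.X.shape[1]) * state.K * W
    gram_bc = (B.T @ B) * (C.T @ C)
    gA = R @ B + lam * (A @ gram_bc - state.unf[0] @ khatri_rao(C, B))
    gram_ac = (A.T @ A) * (C.T @ C)
    gB = R.T @ A + lam * (B @ gram_ac - state.unf[1] @ khatri_rao(C, A))
    return gA, gB


def _init_steps(state: _FitState, A, B, C, W, PPt: np.ndarray, seed: int) -> None:
    """Seed per-block step sizes as 1 / L with L from power iteration."""
    lam, theta = state.hp.lam, state.hp.theta
    d1, d2, _ = state.X.shape
    r = A[0].shape[1]
    t = state.t

    for ti in range(t):
        Q = state.X.transpose(2, 0, 1) * (state.K * W[ti])  # (n, d1, d2)
        QB = np.einsum("nij,jr->nir", Q, B[ti])
        gram = lam * (B[ti].T @ B[ti]) * (C[ti].T @ C[ti])

        def mv_A(v, QB=QB, gram=gram):
            V = v.reshape(d1, r)
            y = np.einsum("nir,ir->n", QB, V)
            return (np.einsum("n,nir->ir", y, QB) + V @ gram).ravel()

        L = power_iteration_norm(mv_A, d1 * r, seed=seed)
        state.step[("A", ti)] = 1.0 / max(L, 1e-12)
        # B block: same structure with roles of A and B exchanged
        QtA = np.einsum("nji,jr->nir", Q, A[ti])
        gram_b = lam * (A[ti].T @ A[ti]) * (C[ti].T @ C[ti])

        def mv_B(v, QtA=QtA, gram=gram_b):
            V = v.reshape(d2, r)
            y = np.einsum("nir,ir->n", QtA, V)
            return (np.einsum("n,nir->ir", y, QtA) + V @ gram).ravel()

        L = power_iteration_norm(mv_B, d2 * r, seed=seed)
        state.step[("B", ti)] = 1.0 / max(L, 1e-12)
        gram_c = lam * (A[ti].T @ A[ti]) * (B[ti].T @ B[ti])
        L = float(np.linalg.eigvalsh(gram_c)[-1]) if r > 1 else float(gram_c[0, 0])
        state.step[("C", ti)] = 1.0 / max(L, 1e-12)

    m = np.stack([((A[ti] @ B[ti].T) * state.K).ravel() for ti in range(t)], axis=1)

    def mv_W(v, m=m, PPt=PPt):
        V = v.reshape(d1 * d2, t)
        out = np.empty_like(V)
        for ti in range(t):
            y = state.Xmat @ (V[:, ti] * m[:, ti]) * state.obs[:, ti]
            out[:, ti] = (state.Xmat.T @ y) * m[:, ti]
        out += 2 * theta * V @ PPt
        return out.ravel()

    L = power_iteration_norm(mv_W, d1 * d2 * t, seed=seed)
    state.step["W"] = 1.0 / max(L, 1e-12)


def fit(X, Y: np.ndarray, hp: TMTLHyperparameters) -> TMTLModel:
    """Fit the joint objective by block proximal gradient descent.

    Parameters
    ----------
    X : SimilarityTensor or (d1, d2, n) array with symmetric slices
    Y : (n, t) score matrix; NaN marks a missing target, which is excluded
        from that time point's empirical loss (the sample still informs the
        CP term through its tensor slice)
    """
    Xarr = _as_array(X)
    names = X.biomarker_names if isinstance(X, SimilarityTensor) else None
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not np.all(np.isfinite(Xarr)):
        raise ValueError("tensor contains non-finite values")
    if np.any(np.isinf(Y)):
        raise ValueError("targets contain infinite values")
    d1, d2, n = Xarr.shape
    if Y.shape[0] != n:
        raise ValueError(f"Y has {Y.shape[0]} rows but the tensor has {n} patients")
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if hp.rank > min(d1, d2):
        raise ValueError(f"rank {hp.rank} exceeds min tensor dimension {min(d1, d2)}")
    t = Y.shape[1]
    alphas = tuple(hp.alphas) if hp.alphas is not None else (0.0,) * max(t - 2, 0)
    if len(alphas) != max(t - 2, 0):
        raise ValueError(f"expected {max(t - 2, 0)} alphas for t={t}, got {len(alphas)}")
    op = build_P(t, alphas) if t >= 2 else None
    hp = replace(hp, alphas=alphas)

    state = _FitState(Xarr, Y, hp)
    A0, B0, C0, _ = cp_als(Xarr, hp.rank, max_iter=hp.init_sweeps, tol=1e-9, seed=hp.seed)
    A = [A0.copy() for _ in range(t)]
    B = [B0.copy() for _ in range(t)]
    C = [C0.copy() for _ in range(t)]
    W = [np.zeros((d1, d2)) for _ in range(t)]
    PPt = op.PPt if op is not None else np.zeros((t, t))

    model = TMTLModel(A=A, B=B, C=C, W=W, K=state.K, hp=hp, smoothness=op,
                      biomarker_names=names)
    trace = [objective_joint(Xarr, Y, model, hp, op)]

    if hp.max_iter > 0:
        _init_steps(state, A, B, C, W, PPt, seed=hp.seed)

    # in shared mode one factor set is tied across all time points, so every
    # time point's empirical loss and t copies of the CP term enter its blocks
    tied = hp.shared_factors
    block_t = (0,) if tied else tuple(range(t))
    for _ in range(hp.max_iter):
        for ti in block_t:
            idxs = tuple(range(t)) if tied else (ti,)

            gA = sum(_factor_grads(state, tj, A[ti], B[ti], C[ti], W[tj])[0] for tj in idxs)

            def fA(Z, ti=ti, idxs=idxs):
                return sum(state.emp_loss(tj, Z, B[ti], W[tj])[0] for tj in idxs) \
                    + len(idxs) * state.cp_loss(Z, B[ti], C[ti])

            A_new = _prox_step(state, ("A", ti), A[ti], gA, fA, hp.beta)
            for tj in idxs:
                A[tj] = A_new

            gB = sum(_factor_grads(state, tj, A[ti], B[ti], C[ti], W[tj])[1] for tj in idxs)

            def fB(Z, ti=ti, idxs=idxs):
                return sum(state.emp_loss(tj, A[ti], Z, W[tj])[0] for tj in idxs) \
                    + len(idxs) * state.cp_loss(A[ti], Z, C[ti])

            B_new = _prox_step(state, ("B", ti), B[ti], gB, fB, hp.beta)
            for tj in idxs:
                B[tj] = B_new

            gram_ab = (A[ti].T @ A[ti]) * (B[ti].T @ B[ti])
            gC = len(idxs) * hp.lam * (C[ti] @ gram_ab
                                       - state.unf[2] @ khatri_rao(B[ti], A[ti]))

            def fC(Z, ti=ti, idxs=idxs):
                return len(idxs) * state.cp_loss(A[ti], B[ti], Z)

            C_new = _prox_step(state, ("C", ti), C[ti], gC, fC, hp.beta)
            for tj in idxs:
                C[tj] = C_new

        # W stack: all time points jointly (smoothness couples the columns)
        m = np.stack([((A[ti] @ B[ti].T) * state.K).ravel() for ti in range(t)], axis=1)
        Wf = np.stack([w.ravel() for w in W], axis=1)
        gW = np.empty_like(Wf)
        for ti in range(t):
            _, resid = state.emp_loss(ti, A[ti], B[ti], W[ti])
            gW[:, ti] = (state.Xmat.T @ resid) * m[:, ti]
        gW += 2 * hp.theta * Wf @ PPt

        def fW(Z):
            tot = 0.0
            for ti in range(t):
                resid = (state.Xmat @ (Z[:, ti] * m[:, ti]) - state.Y0[:, ti]) * state.obs[:, ti]
                tot += 0.5 * float(resid @ resid)
            if op is not None:
                tot += hp.theta * float(np.sum((Z @ op.P) ** 2))
            return tot

        Wf_new = _prox_step(state, "W", Wf, gW, fW, hp.beta)
        for ti in range(t):
            W[ti] = Wf_new[:, ti].reshape(d1, d2)

        model.A, model.B, model.C, model.W = A, B, C, W
        obj = objective_joint(Xarr, Y, model, hp, op)
        trace.append(obj)
        if abs(trace[-2] - obj) <= hp.tol * max(abs(trace[-2]), 1e-12):
            break

    model.objective_trace = trace
    model.fitted = True
    return model


def predict(model: TMTLModel, X_new) -> np.ndarray:
    """Predicted score matrix (n_new, t) for new similarity slices."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    Xarr = _as_array(X_new)
    if Xarr.shape[:2] != model.K.shape:
        raise ValueError(f"feature dims {Xarr.shape[:2]} do not match training {model.K.shape}")
    Xmat = Xarr.transpose(2, 0, 1).reshape(Xarr.shape[2], -1)
    cols = [Xmat @ ((model.A[ti] @ model.B[ti].T) * model.K * model.W[ti]).ravel()
            for ti in range(model.t)]
    return np.stack(cols, axis=1)
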