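"""Metrics, the repeated split/CV protocol, and biomarker-pair ranking.

Performance is reported as the per-time-point root mean squared error (rMSE)
and, across time points, the variance-normalized mean squared error (nMSE)
customary in multi-task regression. The experimental protocol draws repeated
patient-level train/test splits (default 9:1, 20 repeats), selects
hyperparameters by k-fold cross-validation on the training patients, refits
on the full training set, and aggregates mean +/- SD over the repeats. For
interpretability, the fitted weight matrix of a time point is masked to its
upper triangle and the largest-magnitude biomarker pairs are ranked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold, ShuffleSplit

from .boosting_ensemble import fit_ensemble, predict_ensemble
from .similarity_tensor import SimilarityTensor
from .tmtl_model import TMTLHyperparameters

__all__ = [
    "rmse",
    "nmse",
    "EvaluationReport",
    "run_protocol",
    "RelationshipRanking",
    "rank_relationships",
    "write_brainnet",
]


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean squared error over the observed (non-NaN target) entries."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError("no observed targets")
    diff = y[obs] - y_hat[obs]
    return float(np.sqrt(diff @ diff / obs.sum()))


def nmse(Y: np.ndarray, Y_hat: np.ndarray) -> float:
    """Normalized MSE: sum_i ||Y_i - Yhat_i||^2 / sigma(Y_i), over sum_i n_i.

    sigma(Y_i) is the standard deviation of the observed targets at time
    point i; a zero-variance time point makes the metric undefined.
    """
    Y = np.asarray(Y, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y.ndim == 1:
        Y, Y_hat = Y[:, None], Y_hat[:, None]
    if Y.shape != Y_hat.shape:
        raise ValueError("shape mismatch")
    num, count = 0.0, 0
    for i in range(Y.shape[1]):
        obs = ~np.isnan(Y[:, i])
        if not obs.any():
            continue
        sigma = float(np.std(Y[obs, i]))
        if sigma == 0:
            raise ValueError(f"zero target variance at time point {i}")
        diff = Y[obs, i] - Y_hat[obs, i]
        num += float(diff @ diff) / sigma
        count += int(obs.sum())
    if count == 0:
        raise ValueError("no observed targets")
    return num / count


@dataclass
class EvaluationReport:
    """Aggregated results of the repeated split/CV protocol."""

    time_points: tuple
    rmse_mean: np.ndarray
    rmse_sd: np.ndarray
    nmse_mean: float
    nmse_sd: float
    n_repeats: int
    chosen: list            # selected grid index per repeat
    cv_tables: list         # per repeat: list of mean validation rMSE per grid entry
    rmse_per_repeat: np.ndarray
    nmse_per_repeat: np.ndarray
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "time_points": list(self.time_points),
            "rmse_mean": [float(v) for v in self.rmse_mean],
            "rmse_sd": [float(v) for v in self.rmse_sd],
            "nmse_mean": float(self.nmse_mean),
            "nmse_sd": float(self.nmse_sd),
            "n_repeats": self.n_repeats,
            "chosen_grid_index": [int(c) for c in self.chosen],
            "cv_tables": [[float(v) for v in tab] for tab in self.cv_tables],
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary(self) -> str:
        lines = [f"{'time point':>10} {'rMSE mean':>10} {'rMSE SD':>8}"]
        for tp, m, s in zip(self.time_points, self.rmse_mean, self.rmse_sd):
            lines.append(f"{tp:>10} {m:10.4f} {s:8.4f}")
        lines.append(f"nMSE: {self.nmse_mean:.4f} +/- {self.nmse_sd:.4f} "
                     f"({self.n_repeats} repeats)")
        return "\n".join(lines)


def _subset(X, idx) -> SimilarityTensor | np.ndarray:
    if isinstance(X, SimilarityTensor):
        return SimilarityTensor(X.values[:, :, idx], X.interval, X.biomarker_names,
                                tuple(X.patient_ids[i] for i in idx), X.normalized)
    return np.asarray(X)[:, :, idx]


def run_protocol(
    tensors,
    Y: np.ndarray,
    hp_grid,
    n_repeats: int = 20,
    split_ratio: float = 0.9,
    cv_folds: int = 5,
    seed: int = 0,
    time_points: tuple | None = None,
    nu: float = 1.0,
) -> EvaluationReport:
    """Repeated patient-level 9:1 splits with k-fold CV hyperparameter search.

    ``tensors`` is a single similarity tensor (base model) or the
    chronologically ordered list of interval tensors (boosting ensemble);
    splits are over patients, which index both the tensor slices and the
    rows of Y. The grid candidate with the lowest mean validation rMSE
    (averaged over folds and time points) wins; ties go to the earlier entry.
    """
    if isinstance(tensors, SimilarityTensor) or (
        isinstance(tensors, np.ndarray) and tensors.ndim == 3
    ):
        tensors = [tensors]
    tensors = list(tensors)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, t = Y.shape
    hp_grid = list(hp_grid)
    if not hp_grid:
        raise ValueError("empty hyperparameter grid")
    n_test = n - int(round(n * split_ratio))
    if n_test < 1 or n - n_test < cv_folds or (n - n_test) // cv_folds < 2:
        raise ValueError(
            f"degenerate split: n={n}, split_ratio={split_ratio}, cv_folds={cv_folds}"
        )
    tps = tuple(time_points) if time_points is not None else tuple(f"T{i + 1}" for i in range(t))

    rep_seeds = [int(s) for s in
                 np.random.SeedSequence(seed).generate_state(n_repeats) % (2 ** 31)]
    all_rmse = np.zeros((n_repeats, t))
    all_nmse = np.zeros(n_repeats)
    chosen: list[int] = []
    cv_tables: list[list[float]] = []

    for rep, rep_seed in enumerate(rep_seeds):
        splitter = ShuffleSplit(n_splits=1, test_size=n_test, random_state=rep_seed)
        train_idx, test_idx = next(splitter.split(np.arange(n)))

        table = []
        for hp in hp_grid:
            hp_r = replace(hp, seed=rep_seed)
            fold_scores = []
            kf = KFold(n_splits=cv_folds, shuffle=True, random_state=rep_seed)
            for fit_rel, val_rel in kf.split(train_idx):
                fit_idx, val_idx = train_idx[fit_rel], train_idx[val_rel]
                ens = fit_ensemble([_subset(X, fit_idx) for X in tensors],
                                   Y[fit_idx], hp_r, nu=nu)
                pred = predict_ensemble(ens, [_subset(X, val_idx) for X in tensors])
                vals = [rmse(Y[val_idx, ti], pred[:, ti])
                        for ti in range(t) if (~np.isnan(Y[val_idx, ti])).any()]
                fold_scores.append(float(np.mean(vals)))
            table.append(float(np.mean(fold_scores)))
        best = int(np.argmin(table))
        chosen.append(best)
        cv_tables.append(table)

        hp_best = replace(hp_grid[best], seed=rep_seed)
        ens = fit_ensemble([_subset(X, train_idx) for X in tensors], Y[train_idx],
                           hp_best, nu=nu)
        pred = predict_ensemble(ens, [_subset(X, test_idx) for X in tensors])
        all_rmse[rep] = [rmse(Y[test_idx, ti], pred[:, ti]) for ti in range(t)]
        all_nmse[rep] = nmse(Y[test_idx], pred)

    ddof = 1 if n_repeats > 1 else 0
    return EvaluationReport(
        time_points=tps,
        rmse_mean=all_rmse.mean(axis=0),
        rmse_sd=all_rmse.std(axis=0, ddof=ddof),
        nmse_mean=float(all_nmse.mean()),
        nmse_sd=float(all_nmse.std(ddof=ddof)),
        n_repeats=n_repeats,
        chosen=chosen,
        cv_tables=cv_tables,
        rmse_per_repeat=all_rmse,
        nmse_per_repeat=all_nmse,
        seed=seed,
    )


@dataclass(frozen=True)
class RelationshipRanking:
    """Top-k biomarker pairs of one time point, by weight magnitude."""

    pairs: tuple           # ((name_i, name_j, weight), ...), |weight| descending
    time_point: str = ""

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)


def rank_relationships(W_t: np.ndarray, names, K: np.ndarray, k: int = 10,
                       time_point: str = "") -> RelationshipRanking:
    """Rank upper-triangular weight entries by |weight|, descending.

    The signed weight is reported; ties break on the (row, column) index so
    the ordering is stable.
    """
    W_t = np.asarray(W_t, dtype=float)
    names = list(names)
    masked = W_t * K
    ii, jj = np.nonzero(K)
    n_pairs = len(ii)
    if k > n_pairs:
        raise ValueError(f"k={k} exceeds the {n_pairs} available pairs")
    w = masked[ii, jj]
    order = np.lexsort((jj, ii, -np.abs(w)))[:k]
    pairs = tuple((names[ii[o]], names[jj[o]], float(w[o])) for o in order)
    return RelationshipRanking(pairs=pairs, time_point=time_point)


def write_brainnet(ranking: RelationshipRanking, names, path_prefix,
                   categories: dict | None = None) -> None:
    """Export a ranking as BrainNet-Viewer-style .node/.edge text files.

    Without atlas coordinates the nodes are laid out on a unit circle; the
    node color column encodes the biomarker category, the edge weights the
    |weight| of each ranked pair.
    """
    names = list(names)
    d = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    cats = categories or {}
    cat_codes = {c: i + 1 for i, c in enumerate(sorted(set(cats.values())))}
    angles = 2 * np.pi * np.arange(d) / max(d, 1)
    with open(str(path_prefix) + ".node", "w") as fh:
        for i, nm in enumerate(names):
            color = cat_codes.get(cats.get(nm, ""), 1)
            fh.write(f"{np.cos(angles[i]):.4f}\t{np.sin(angles[i]):.4f}\t0.0000\t"
                     f"{color}\t1\t{nm}\n")
    edges = np.zeros((d, d))
    for nm_i, nm_j, w in ranking:
        i, j = idx[nm_i], idx[nm_j]
        edges[i, j] = edges[j, i] = abs(w)
    with open(str(path_prefix) + ".edge", "w") as fh:
        for row in edges:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")
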