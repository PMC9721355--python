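"""Biomarker-variation vectors and the Mahalanobis similarity tensor.

For each patient and biomarker, two consecutive scans give a 2-vector
describing the morphological variation trend: the dimensionless rate of
change ``(x_late - x_early) / x_early`` and the velocity
``(x_late - x_early) / months`` (a month is 30.4375 days). The pairwise
Mahalanobis distances among a patient's ``d`` variation vectors form one
symmetric ``d x d`` slice; stacking patients yields the ``d x d x n`` tensor
that the downstream regression consumes. Because each slice is symmetric
with a zero diagonal, a strictly upper-triangular binary mask ``K`` removes
the duplicated half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .preprocess_io import LongitudinalCohort

__all__ = [
    "MONTH_DAYS",
    "VariationVector",
    "SimilarityTensor",
    "variation_vector",
    "variation_matrix",
    "regularize_covariance",
    "mahalanobis",
    "build_similarity_tensor",
    "correction_mask",
]

#: Mean Gregorian month length in days; used for the velocity denominator.
MONTH_DAYS = 30.4375


@dataclass(frozen=True)
class VariationVector:
    """Per-(patient, biomarker) morphological variation trend."""

    rate_of_change: float
    velocity: float  # per month

    def as_array(self) -> np.ndarray:
        return np.array([self.rate_of_change, self.velocity])


@dataclass(frozen=True)
class SimilarityTensor:
    """``d x d x n`` stack of per-patient biomarker-pair distance matrices."""

    values: np.ndarray
    interval: tuple[str, str]
    biomarker_names: tuple[str, ...]
    patient_ids: tuple
    normalized: bool = True

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValueError(f"expected (d, d, n) tensor, got shape {v.shape}")
        if v.shape[2] != len(self.patient_ids):
            raise ValueError("patient axis does not match patient_ids")

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[2]

    def slice(self, k: int) -> np.ndarray:
        return self.values[:, :, k]

    def reorder(self, patient_ids) -> "SimilarityTensor":
        """Return a tensor with the patient axis aligned to ``patient_ids``."""
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        idx = [pos[p] for p in patient_ids]
        return SimilarityTensor(
            self.values[:, :, idx], self.interval, self.biomarker_names,
            tuple(patient_ids), self.normalized,
        )

    def save(self, path) -> None:
        """Write the array (.npz) plus a JSON sidecar with the metadata."""
        path = str(path)
        np.savez_compressed(path if path.endswith(".npz") else path + ".npz", values=self.values)
        sidecar = {
            "interval": list(self.interval),
            "biomarker_names": list(self.biomarker_names),
            "patient_ids": [str(p) for p in self.patient_ids],
            "normalized": self.normalized,
        }
        with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SimilarityTensor":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        values = np.load(base + ".npz")["values"]
        with open(base + ".json") as fh:
            meta = json.load(fh)
        return cls(values, tuple(meta["interval"]), tuple(meta["biomarker_names"]),
                   tuple(meta["patient_ids"]), meta["normalized"])


def variation_vector(x_early: float, x_late: float, t_early, t_late) -> VariationVector:
    """Rate of change and monthly velocity between two consecutive scans."""
    months = (pd.Timestamp(t_late) - pd.Timestamp(t_early)).days / MONTH_DAYS
    if months <= 0:
        raise ValueError("later visit must be strictly after the earlier one")
    if x_early == 0:
        raise ZeroDivisionError("rate of change undefined for zero baseline value")
    delta = x_late - x_early
    return VariationVector(delta / x_early, delta / months)


def variation_matrix(
    cohort: LongitudinalCohort,
    interval: tuple[str, str] = ("BL", "M06"),
    zero_baseline: str = "error",
) -> tuple[np.ndarray, list]:
    """(n, d, 2) array of variation vectors for one scan interval.

    ``zero_baseline`` controls biomarkers whose earlier value is exactly zero:
    ``"error"`` (FreeSurfer features are positive, so a zero signals a data
    problem) or ``"nan"`` (rate set missing; distances for that biomarker fall
    back to the velocity component alone).
    """
    early, late = interval
    missing = [p for p in cohort.patients if p not in set(cohort.patients_with_visits(interval))]
    if missing:
        raise ValueError(
            f"{len(missing)} patients lack the {early}->{late} scans "
            "(apply filter_patients_followup_mri first)"
        )
    fe = cohort.visit_frame(early)
    fl = cohort.visit_frame(late)
    patients = cohort.patients
    cols = list(cohort.biomarker_names)
    xe = fe.loc[patients, cols].to_numpy(dtype=float)
    xl = fl.loc[patients, cols].to_numpy(dtype=float)
    days = (
        pd.to_datetime(fl.loc[patients, "exam_date"]).to_numpy()
        - pd.to_datetime(fe.loc[patients, "exam_date"]).to_numpy()
    ) / np.timedelta64(1, "D")
    if (days <= 0).any():
        raise ValueError("non-positive time gap between consecutive scans")
    months = days / MONTH_DAYS
    delta = xl - xe
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = delta / xe
    if (xe == 0).any():
        if zero_baseline == "error":
            bad = np.argwhere(xe == 0)[0]
            raise ZeroDivisionError(
                f"zero baseline for patient {patients[bad[0]]!r}, biomarker {cols[bad[1]]!r}"
            )
        rate[xe == 0] = np.nan
    velocity = delta / months[:, None]
    return np.stack([rate, velocity], axis=-1), patients


def regularize_covariance(S: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Ridge-regularize a 2x2 covariance so it is safely invertible.

    Adds ``eps * trace(S)/2`` to the diagonal; a zero-trace S (all variation
    vectors identical) degenerates to the identity, under which all pairwise
    distances are zero anyway.
    """
    S = np.asarray(S, dtype=float)
    tr = np.trace(S)
    if tr <= 0:
        return np.eye(S.shape[0])
    return S + eps * (tr / S.shape[0]) * np.eye(S.shape[0])


def mahalanobis(x_i, x_j, S: np.ndarray) -> float:
    """Mahalanobis distance sqrt((xi-xj)^T S^-1 (xi-xj)) between two vectors."""
    xi = x_i.as_array() if isinstance(x_i, VariationVector) else np.asarray(x_i, dtype=float)
    xj = x_j.as_array() if isinstance(x_j, VariationVector) else np.asarray(x_j, dtype=float)
    diff = xi - xj
    q = diff @ np.linalg.solve(S, diff)
    if not np.isfinite(q):
        raise np.linalg.LinAlgError("covariance matrix is numerically singular")
    return float(np.sqrt(max(q, 0.0)))


def _slice_distances(V: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Pairwise Mahalanobis distances among the rows of V (d, 2) under S."""
    nan_rate = np.isnan(V[:, 0])
    VI = np.linalg.inv(S)
    if not nan_rate.any():
        return cdist(V, V, metric="mahalanobis", VI=VI)
    D = np.zeros((len(V), len(V)))
    ok = ~nan_rate
    if ok.any():
        D[np.ix_(ok, ok)] = cdist(V[ok], V[ok], metric="mahalanobis", VI=VI)
    # pairs touching a missing rate: 1-D Mahalanobis on velocity alone
    sv = np.sqrt(S[1, 1])
    for i in np.where(nan_rate)[0]:
        dv = np.abs(V[i, 1] - V[:, 1]) / sv
        D[i, :] = dv
        D[:, i] = dv
    return D


def build_similarity_tensor(
    cohort: LongitudinalCohort,
    interval: tuple[str, str] = ("BL", "M06"),
    covariance_scope: str = "per-patient",
    normalize: bool = True,
    eps: float = 1e-6,
    zero_baseline: str = "error",
) -> SimilarityTensor:
    """Assemble the symmetric Mahalanobis similarity tensor for one interval.

    ``covariance_scope`` selects the population for the 2x2 covariance S of
    the (rate, velocity) vectors: ``"per-patient"`` estimates S from that
    patient's own d biomarker vectors (each slice gets its own metric);
    ``"pooled"`` shares one S estimated from all patients' vectors. With
    ``normalize`` each slice is min-max scaled to [0, 1].
    """
    V, patients = variation_matrix(cohort, interval, zero_baseline=zero_baseline)
    n, d, _ = V.shape
    if d < 2:
        raise ValueError("need at least 2 biomarkers to form pairwise distances")
    if covariance_scope == "per-patient" and d < 3:
        raise ValueError("per-patient covariance needs d >= 3 biomarkers")
    if covariance_scope == "pooled":
        flat = V.reshape(-1, 2)
        flat = flat[~np.isnan(flat).any(axis=1)]
        S_shared = regularize_covariance(np.cov(flat, rowvar=False), eps)
    elif covariance_scope != "per-patient":
        raise ValueError("covariance_scope must be 'per-patient' or 'pooled'")

    X = np.zeros((d, d, n))
    for k in range(n):
        Vk = V[k]
        if covariance_scope == "per-patient":
            obs = Vk[~np.isnan(Vk).any(axis=1)]
            S = regularize_covariance(np.cov(obs, rowvar=False), eps)
        else:
            S = S_shared
        D = _slice_distances(Vk, S)
        np.fill_diagonal(D, 0.0)
        if normalize:
            top = D.max()
            if top > 0:
                D = (D - D.min()) / (top - D.min())
        X[:, :, k] = D
    return SimilarityTensor(X, tuple(interval), tuple(cohort.biomarker_names),
                            tuple(patients), normalized=normalize)


def correction_mask(d1: int, d2: int) -> np.ndarray:
    """Strictly upper-triangular ones matrix K removing duplicated pairs.

    For a symmetric zero-diagonal M, ``(K * M).sum() == M.sum() / 2``.
    """
    if d1 < 1 or d2 < 1:
        raise ValueError("mask dimensions must be positive")
    return np.triu(np.ones((d1, d2)), k=1)
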