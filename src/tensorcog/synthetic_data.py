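"""Synthetic longitudinal cohorts with known ground truth.

Real cohorts of this kind (FreeSurfer features over BL/M06/M12/M24 visits
with AD/MCI/CN labels and MMSE/ADAS-Cog follow-up) sit behind registration
gates, so the generator emulates their statistical shape end to end:

* biomarker trajectories ``x(v) = baseline * (1 + rate * months + noise)``
  with per-(group, biomarker) monthly rates — atrophy-sensitive categories
  (cortical volume, thickness mean/SD) decline faster in AD than MCI than
  CN, while surface area and white-matter volume drift similarly across
  groups;
* exam dates at the nominal month with a uniform jitter of up to 15 days;
* optional feature-, visit- and score-level missingness;
* cognitive scores produced by the model's own forward rule: a sparse
  upper-triangular weight stack W* (temporally smooth across prediction
  time points) and CP factors A*, B* of the actual similarity tensor give
  the noiseless score, plus homoscedastic Gaussian noise scaled to a
  fraction of the signal SD.

Because the targets follow the forward model exactly, fitting the estimator
on generated data is a parameter-recovery experiment with a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess_io import (
    BIOMARKER_CATEGORIES,
    TIME_POINTS,
    LongitudinalCohort,
    ScoreTable,
)
from .similarity_tensor import MONTH_DAYS, SimilarityTensor, build_similarity_tensor, correction_mask
from .tensor_ops import cp_als

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_trajectories",
           "make_truth", "generate_targets", "make_regression_problem"]

#: Monthly fractional decline means per diagnosis group for atrophy-sensitive
#: categories (CV, TA, TS); stable categories (SV, SA) share the CN mean.
_GROUP_RATE_MEAN = {"AD": -0.004, "MCI": -0.002, "CN": -0.0005}
_RATE_BETWEEN_SD = 0.0015   # biomarker-to-biomarker spread of the group mean rate
_RATE_WITHIN_SD = 0.0008    # patient-to-patient spread around it

_BASELINE_SCALE = {  # (mean, sd) of baseline values per category
    "CV": (5000.0, 1000.0),   # mm^3
    "SV": (8000.0, 1500.0),   # mm^3
    "SA": (2500.0, 500.0),    # mm^2
    "TA": (2.5, 0.3),         # mm
    "TS": (0.6, 0.1),         # mm
}

_ATROPHY_CATEGORIES = ("CV", "TA", "TS")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of the generator."""

    n: int = 100
    d: int = 20
    visits: tuple = ("BL", "M06", "M12", "M24")
    group_props: dict = field(default_factory=lambda: {"AD": 0.3, "MCI": 0.4, "CN": 0.3})
    rank: int = 3
    n_time_points: int = 4
    w_density: float = 0.05       # fraction of upper-triangular pairs with signal
    w_scale: float = 1.0
    w_drift: float = 0.1          # SD of the support-wise drift between adjacent time points
    biomarker_noise_sd: float = 0.005   # relative measurement noise per cell
    score_noise_frac: float = 0.1       # score noise SD as a fraction of signal SD
    date_jitter_days: int = 15
    feature_missing_rate: float = 0.0
    visit_missing_rate: float = 0.0
    score_missing_rate: float = 0.0
    interval_weights: tuple = (1.0,)    # signal weight of each scan interval in the targets
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_props.values()) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        for r in (self.w_density, self.feature_missing_rate, self.visit_missing_rate,
                  self.score_missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_time_points > len(TIME_POINTS):
            raise ValueError(f"at most {len(TIME_POINTS)} prediction time points")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort (one entry per scan interval)."""

    W: list       # (d, d, t) sparse upper-triangular weight stacks
    A: list       # (d, r) latent factors of each interval tensor
    B: list
    C: list       # (n, r)
    groups: np.ndarray | None = None
    noiseless_scores: np.ndarray | None = None  # (n, t)


def _biomarker_names(d: int) -> tuple[list[str], dict]:
    names, cats = [], {}
    for i in range(d):
        cat = BIOMARKER_CATEGORIES[i % len(BIOMARKER_CATEGORIES)]
        nm = f"{cat}_roi{i:03d}"
        names.append(nm)
        cats[nm] = cat
    return names, cats


def generate_trajectories(spec: SyntheticSpec, return_rates: bool = False):
    """Simulate the per-(patient, visit) biomarker table.

    With ``return_rates`` also returns the (n, d) matrix of true monthly
    rates, so tests can check the trajectories in closed form: with zero
    measurement noise the rate of change over BL->M06 is exactly six times
    the monthly rate, independent of date jitter.
    """
    rng = np.random.default_rng(spec.seed)
    names, cats = _biomarker_names(spec.d)
    groups = rng.choice(list(spec.group_props), size=spec.n,
                        p=list(spec.group_props.values()))

    # group-level mean monthly rate per biomarker, then patient-level rates
    rate_mean = np.zeros((len(spec.group_props), spec.d))
    group_list = list(spec.group_props)
    for gi, g in enumerate(group_list):
        for bi, nm in enumerate(names):
            mu = _GROUP_RATE_MEAN[g] if cats[nm] in _ATROPHY_CATEGORIES \
                else _GROUP_RATE_MEAN["CN"]
            rate_mean[gi, bi] = mu + rng.normal(0, _RATE_BETWEEN_SD)
    gidx = np.array([group_list.index(g) for g in groups])
    rates = rate_mean[gidx] + rng.normal(0, _RATE_WITHIN_SD, size=(spec.n, spec.d))

    baselines = np.empty((spec.n, spec.d))
    for bi, nm in enumerate(names):
        mu, sd = _BASELINE_SCALE[cats[nm]]
        baselines[:, bi] = np.maximum(rng.normal(mu, sd, size=spec.n), 0.05 * mu)

    month_of = {"BL": 0, "M06": 6, "M12": 12, "M24": 24}
    start = pd.Timestamp("2010-01-01")
    rows = []
    for k in range(spec.n):
        pid = f"P{k:04d}"
        bl_date = start + pd.Timedelta(days=int(rng.integers(0, 365)))
        for v in spec.visits:
            if v != "BL" and spec.visit_missing_rate > 0 \
                    and rng.random() < spec.visit_missing_rate:
                continue
            months = month_of[v]
            jitter = 0 if v == "BL" else int(rng.integers(-spec.date_jitter_days,
                                                          spec.date_jitter_days + 1))
            date = bl_date + pd.Timedelta(days=round(months * MONTH_DAYS) + jitter)
            noise = rng.normal(0, spec.biomarker_noise_sd, size=spec.d)
            vals = baselines[k] * (1 + rates[k] * months + noise)
            if spec.feature_missing_rate > 0:
                vals = vals.copy()
                vals[rng.random(spec.d) < spec.feature_missing_rate] = np.nan
            rows.append([pid, v, date, groups[k], *vals])
    df = pd.DataFrame(rows, columns=["patient_id", "visit_code", "exam_date", "group"] + names)
    cohort = LongitudinalCohort(df, tuple(names), cats)
    return (cohort, rates) if return_rates else cohort


def _sparse_smooth_W(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """(d, d, t) upper-triangular sparse stack, smooth across time points."""
    d, t = spec.d, spec.n_time_points
    K = correction_mask(d, d)
    ii, jj = np.nonzero(K)
    n_pairs = len(ii)
    m = max(1, int(round(spec.w_density * n_pairs)))
    support = rng.choice(n_pairs, size=m, replace=False)
    W = np.zeros((d, d, t))
    vals = rng.normal(0, spec.w_scale, size=m)
    vals += np.sign(vals) * 0.5 * spec.w_scale  # keep signals away from zero
    for ti in range(t):
        if ti > 0:
            vals = vals + rng.normal(0, spec.w_drift * spec.w_scale, size=m)
        W[ii[support], jj[support], ti] = vals
    return W


def make_truth(spec: SyntheticSpec, tensors) -> SyntheticTruth:
    """Draw ground-truth weights and extract CP factors of each tensor."""
    rng = np.random.default_rng(spec.seed + 1)
    truth = SyntheticTruth(W=[], A=[], B=[], C=[])
    for s, X in enumerate(tensors):
        arr = X.values if isinstance(X, SimilarityTensor) else np.asarray(X)
        A, B, C, _ = cp_als(arr, spec.rank, max_iter=200, tol=1e-10, seed=spec.seed + 10 + s)
        truth.A.append(A)
        truth.B.append(B)
        truth.C.append(C)
        truth.W.append(_sparse_smooth_W(spec, rng))
    return truth


def generate_targets(spec: SyntheticSpec, tensors, truth: SyntheticTruth,
                     patient_ids=None, kind: str = "synthetic",
                     clip_to_range: bool = False) -> ScoreTable:
    """Scores from the forward model on the interval tensors, plus noise.

    The noiseless score of patient k at time point ti sums, over the scan
    intervals s with ``interval_weights[s] != 0``, the masked bilinear form
    ``sum_ij [(A*_s B*_s^T) * K * W*_s[:, :, ti] * X_s,k]_ij``. Gaussian
    noise with SD ``score_noise_frac`` times the per-time-point signal SD is
    added on top.
    """
    rng = np.random.default_rng(spec.seed + 2)
    arrs = [X.values if isinstance(X, SimilarityTensor) else np.asarray(X) for X in tensors]
    n = arrs[0].shape[2]
    t = spec.n_time_points
    d = arrs[0].shape[0]
    K = correction_mask(d, d)
    weights = spec.interval_weights
    noiseless = np.zeros((n, t))
    for s, arr in enumerate(arrs):
        wgt = weights[s] if s < len(weights) else 0.0
        if wgt == 0.0:
            continue
        Xmat = arr.transpose(2, 0, 1).reshape(n, -1)
        M = (truth.A[s] @ truth.B[s].T) * K
        for ti in range(t):
            noiseless[:, ti] += wgt * (Xmat @ (M * truth.W[s][:, :, ti]).ravel())
    sd = noiseless.std(axis=0)
    noise = rng.normal(0, 1, size=(n, t)) * (spec.score_noise_frac * sd)
    scores = noiseless + noise
    if clip_to_range:
        scores = np.clip(scores, 0.0, 30.0)
    if spec.score_missing_rate > 0:
        scores = scores.copy()
        scores[rng.random(scores.shape) < spec.score_missing_rate] = np.nan
    truth.noiseless_scores = noiseless
    if patient_ids is None:
        patient_ids = [f"P{k:04d}" for k in range(n)]
    wide = pd.DataFrame(scores, index=pd.Index(patient_ids, name="patient_id"),
                        columns=list(TIME_POINTS[:t]))
    return ScoreTable(wide, kind=kind)


def make_regression_problem(
    spec: SyntheticSpec,
    n_intervals: int = 1,
    covariance_scope: str = "per-patient",
    normalize: bool = True,
):
    """End-to-end convenience: cohort -> tensors -> truth -> targets.

    Returns ``(cohort, tensors, Y, truth)`` with Y the (n, t) score matrix
    aligned to the tensor patient axis.
    """
    all_intervals = (("BL", "M06"), ("M06", "M12"), ("M12", "M24"))
    if not 1 <= n_intervals <= len(all_intervals):
        raise ValueError(f"n_intervals must be in [1, {len(all_intervals)}]")
    cohort = generate_trajectories(spec)
    tensors = [build_similarity_tensor(cohort, interval, covariance_scope, normalize)
               for interval in all_intervals[:n_intervals]]
    truth = make_truth(spec, tensors)
    truth.groups = np.array(
        [cohort.visit_frame("BL").loc[p, "group"] for p in tensors[0].patient_ids]
    )
    scores = generate_targets(spec, tensors, truth, patient_ids=tensors[0].patient_ids)
    Y = scores.matrix(tensors[0].patient_ids)
    return cohort, tensors, Y, truth
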