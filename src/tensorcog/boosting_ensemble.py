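"""Gradient-boosting ensemble over consecutive scan intervals.

Patients accumulate MRI scans over time, so consecutive visit pairs
(BL->M06, M06->M12, M12->M24) each yield their own similarity tensor. The
ensemble fits one tensor regression per interval, stagewise: the first stage
fits the score matrix Y, every later stage fits the residual of the
cumulative prediction so far. At prediction time the stages are summed up to
however many scans a patient has — the dynamic-prediction use case where a
forecast sharpens as new detections arrive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity_tensor import SimilarityTensor
from .tmtl_model import TMTLHyperparameters, TMTLModel, fit, predict

__all__ = ["BoostingEnsemble", "fit_ensemble", "predict_ensemble"]


@dataclass
class BoostingEnsemble:
    """Ordered (interval, model) stages plus the shrinkage factor."""

    stages: list  # [(interval, TMTLModel), ...] chronologically ordered
    nu: float = 1.0
    first_stage_unshrunk: bool = True
    patient_ids: tuple = ()

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def stage_factor(self, s: int) -> float:
        return 1.0 if (s == 0 and self.first_stage_unshrunk) else self.nu

    @property
    def intervals(self) -> list:
        return [interval for interval, _ in self.stages]


def _tensor_array(X) -> np.ndarray:
    return X.values if isinstance(X, SimilarityTensor) else np.asarray(X, dtype=float)


def _check_alignment(tensors) -> tuple:
    ids = None
    for X in tensors:
        if isinstance(X, SimilarityTensor):
            if ids is None:
                ids = X.patient_ids
            elif X.patient_ids != ids:
                raise ValueError("tensors do not share the same patient set and ordering")
    n = {_tensor_array(X).shape[2] for X in tensors}
    if len(n) != 1:
        raise ValueError(f"tensors have differing patient counts {sorted(n)}")
    return ids if ids is not None else ()


def fit_ensemble(
    tensors,
    Y: np.ndarray,
    hp: TMTLHyperparameters,
    nu: float = 1.0,
    first_stage_unshrunk: bool = True,
) -> BoostingEnsemble:
    """Fit the stagewise residual ensemble.

    ``tensors`` is the chronologically ordered list of interval tensors; all
    must share the patient axis with Y. Stage s > 1 fits
    ``Y - sum_{u<s} factor_u * prediction_u`` (missing Y entries stay
    missing in every residual). ``nu`` in (0, 1] shrinks the contribution of
    each stage; by default the first stage is left unshrunk so a one-stage
    ensemble is exactly the base model.
    """
    if not 0 < nu <= 1:
        raise ValueError("nu must be in (0, 1]")
    tensors = list(tensors)
    if not tensors:
        raise ValueError("need at least one tensor")
    ids = _check_alignment(tensors)
    Y = np.asarray(Y, dtype=float)

    ens = BoostingEnsemble([], nu=nu, first_stage_unshrunk=first_stage_unshrunk,
                           patient_ids=ids)
    residual = Y.copy()
    for s, X in enumerate(tensors):
        interval = X.interval if isinstance(X, SimilarityTensor) else (f"stage{s}", f"stage{s + 1}")
        model = fit(X, residual, hp)
        ens.stages.append((interval, model))
        residual = residual - ens.stage_factor(s) * predict(model, X)
    return ens


def predict_ensemble(ens: BoostingEnsemble, tensors, upto_stage: int | None = None) -> np.ndarray:
    """Cumulative prediction of the first ``upto_stage`` stages.

    Dynamic prediction: a patient with only k scan intervals available is
    scored with ``upto_stage=k``.
    """
    upto = ens.n_stages if upto_stage is None else upto_stage
    if not 1 <= upto <= ens.n_stages:
        raise ValueError(f"upto_stage must be in [1, {ens.n_stages}]")
    tensors = list(tensors)
    if len(tensors) < upto:
        raise ValueError(f"need {upto} tensors, got {len(tensors)}")
    total = None
    for s in range(upto):
        _, model = ens.stages[s]
        pred = ens.stage_factor(s) * predict(model, tensors[s])
        total = pred if total is None else total + pred
    return total
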