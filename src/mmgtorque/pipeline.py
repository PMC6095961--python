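"""High-level glue: cohort → features → trained variants → evaluation.

Each trial is feature-extracted and normalized independently (per-trial
maxima), then pooled into one sample matrix.  Two model variants are
supported:

* ``"rms"`` — normalized RMS as the single input;
* ``"rms_zc"`` — normalized RMS and normalized ZC.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import ann, evaluation, features
from .errors import InputError, ParameterError
from .features import EpochFeatureSeries
from .synthetic import SyntheticSession

VARIANT_INPUTS = {
    "rms": ("rms_norm",),
    "rms_zc": ("rms_norm", "zc_norm"),
}


def variant_inputs(variant: str) -> tuple:
    try:
        return VARIANT_INPUTS[variant]
    except KeyError:
        raise ParameterError(
            f"unknown model variant {variant!r}; choose from "
            f"{sorted(VARIANT_INPUTS)}"
        ) from None


def session_features(session: SyntheticSession, epoch_s: float = 1.0,
                     band=(20.0, 200.0)) -> EpochFeatureSeries:
    return features.extract_features(session.recording, epoch_s=epoch_s,
                                     band=band)


def feature_matrix(feats: EpochFeatureSeries, variant: str) -> np.ndarray:
    """Per-trial max-normalized input matrix for one trial."""
    cols = []
    for name in variant_inputs(variant):
        if name == "rms_norm":
            cols.append(features.normalize_max(feats.rms).values)
        elif name == "zc_norm":
            cols.append(features.normalize_max(feats.zc.astype(float)).values)
    return np.column_stack(cols)


def torque_targets(feats: EpochFeatureSeries) -> np.ndarray:
    """Per-trial max-normalized torque targets."""
    if feats.torque is None:
        raise InputError("trial has no torque channel to train against")
    return features.normalize_max(feats.torque).values


def build_dataset(sessions: Sequence[SyntheticSession], variant: str,
                  epoch_s: float = 1.0, band=(20.0, 200.0)):
    """Pooled (X, y) over trials, each trial normalized independently."""
    Xs, ys = [], []
    for s in sessions:
        feats = session_features(s, epoch_s=epoch_s, band=band)
        Xs.append(feature_matrix(feats, variant))
        ys.append(torque_targets(feats))
    return np.vstack(Xs), np.concatenate(ys)


def train_variant(sessions: Sequence[SyntheticSession], variant: str,
                  hidden_n: int = 10, seed: int = 0,
                  cfg: Optional[ann.TrainConfig] = None):
    """Train one model variant on a list of extension sessions."""
    X, y = build_dataset(sessions, variant)
    model = ann.init_model(variant_inputs(variant), hidden_n=hidden_n,
                           seed=seed)
    if cfg is None:
        cfg = ann.TrainConfig(seed=seed)
    return ann.lm_train(model, X, y, cfg)


def predict_session(model: ann.MLPModel, feats: EpochFeatureSeries):
    """Predicted normalized torque over one trial's epochs."""
    variant = "rms_zc" if "zc_norm" in model.input_names else "rms"
    return ann.forward(model, feature_matrix(feats, variant))


def evaluate_sessions(model: ann.MLPModel,
                      sessions: Sequence[SyntheticSession],
                      drop: float = 0.5, smooth_s: float = 5.0):
    """Per-session :class:`~mmgtorque.evaluation.EvaluationReport` list."""
    reports = []
    for s in sessions:
        feats = session_features(s)
        pred = predict_session(model, feats)
        actual = torque_targets(feats)
        reports.append(
            evaluation.evaluate_prediction(pred, actual, feats.t,
                                           drop=drop, smooth_s=smooth_s)
        )
    return reports


def standing_evaluations(models: dict,
                         sessions: Sequence[SyntheticSession]):
    """Build :class:`~mmgtorque.evaluation.StandingSession` records.

    ``models`` maps variant name → trained model; each standing session
    gets predictions from every variant over a common epoch grid.
    """
    out = []
    for s in sessions:
        feats = session_features(s)
        rms_n = features.normalize_max(feats.rms).values
        zc_n = features.normalize_max(feats.zc.astype(float)).values
        pred = {v: predict_session(m, feats) for v, m in models.items()}
        out.append(
            evaluation.StandingSession(
                label=s.recording.label, t=feats.t,
                rms_norm=rms_n, zc_norm=zc_n, pred=pred,
            )
        )
    return out
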