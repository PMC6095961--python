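"""Single-hidden-layer perceptron trained with Levenberg–Marquardt.

The regressor maps normalized MMG features (RMS alone, or RMS and ZC) to
normalized knee torque.  Architecture: 10 logistic-sigmoid hidden units and
one linear output,

    z = W2 · σ(W1 u + b1) + b2 .

Training minimizes the sum of squared residuals e = R − z (R the measured
normalized torque) with the damped Gauss–Newton update

    Δw = [JᵀJ + μI]⁻¹ Jᵀ e ,

where J is the analytic Jacobian ∂z/∂w over all weights and biases and μ
interpolates between Gauss–Newton (μ → 0) and scaled gradient descent
(μ large).  A step is accepted only if it reduces the training SSE; on
acceptance μ is divided by ``mu_down``, on rejection multiplied by
``mu_up`` and the step retried.  Training stops on any of: epoch budget,
gradient norm below ``grad_tol``, μ overflow, or ``max_val_failures``
consecutive validation-SSE increases (early stopping).  The weights from
the best validation epoch are returned.

Data are split 70/15/15 into train/validation/test partitions by a seeded
per-sample shuffle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ModelLoadError, ParameterError, TrainingError

VALID_INPUTS = ("rms_norm", "zc_norm")

MODEL_FORMAT = "mmgtorque-mlp/1"


def _sigmoid(a: np.ndarray) -> np.ndarray:
    # numerically safe logistic
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


@dataclass
class MLPModel:
    """Weights of the 1-hidden-layer network.

    ``W1`` is (hidden_n, n_inputs), ``b1`` (hidden_n,), ``W2``
    (1, hidden_n), ``b2`` scalar.  ``input_names`` records which feature
    columns the model consumes, in order.
    """

    input_names: tuple
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: float
    hidden_n: int = 10
    training_seed: Optional[int] = None

    def __post_init__(self):
        self.input_names = tuple(self.input_names)
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float).reshape(1, -1)
        self.b2 = float(self.b2)
        if self.hidden_n < 1:
            raise ParameterError("hidden_n must be >= 1")
        d = len(self.input_names)
        if self.W1.shape != (self.hidden_n, d):
            raise ParameterError(
                f"W1 shape {self.W1.shape} != ({self.hidden_n}, {d})"
            )
        if self.b1.shape != (self.hidden_n,):
            raise ParameterError(f"b1 shape {self.b1.shape} != ({self.hidden_n},)")
        if self.W2.shape != (1, self.hidden_n):
            raise ParameterError(f"W2 shape {self.W2.shape} != (1, {self.hidden_n})")

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + 1


def init_model(input_names: Sequence[str], hidden_n: int = 10,
               seed: int = 0) -> MLPModel:
    """Seeded uniform [−0.5, 0.5] initialization."""
    input_names = tuple(input_names)
    if not input_names:
        raise ParameterError("input_names must be nonempty")
    for name in input_names:
        if name not in VALID_INPUTS:
            raise ParameterError(
                f"unknown input {name!r}; valid inputs: {VALID_INPUTS}"
            )
    rng = np.random.default_rng(seed)
    d = len(input_names)
    return MLPModel(
        input_names=input_names,
        W1=rng.uniform(-0.5, 0.5, size=(hidden_n, d)),
        b1=rng.uniform(-0.5, 0.5, size=hidden_n),
        W2=rng.uniform(-0.5, 0.5, size=(1, hidden_n)),
        b2=float(rng.uniform(-0.5, 0.5)),
        hidden_n=hidden_n,
        training_seed=seed,
    )


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def forward(model: MLPModel, inputs) -> np.ndarray:
    """Network output for one or more feature rows.

    Output is unclipped: predictions may leave [0, 1].
    """
    X = _as_2d(inputs)
    if X.shape[1] != len(model.input_names):
        raise ParameterError(
            f"input has {X.shape[1]} columns, model expects "
            f"{len(model.input_names)}"
        )
    h = _sigmoid(X @ model.W1.T + model.b1)
    return (h @ model.W2.ravel()) + model.b2


# -- weight vector packing ---------------------------------------------------

def _pack(model: MLPModel) -> np.ndarray:
    return np.concatenate(
        [model.W1.ravel(), model.b1, model.W2.ravel(), [model.b2]]
    )


def _unpack(model: MLPModel, w: np.ndarray) -> MLPModel:
    d = len(model.input_names)
    h = model.hidden_n
    i = 0
    W1 = w[i : i + h * d].reshape(h, d); i += h * d
    b1 = w[i : i + h]; i += h
    W2 = w[i : i + h].reshape(1, h); i += h
    b2 = float(w[i])
    return MLPModel(
        input_names=model.input_names, W1=W1, b1=b1, W2=W2, b2=b2,
        hidden_n=h, training_seed=model.training_seed,
    )


def output_jacobian(model: MLPModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (z, ∂z/∂w) for each input row.

    Column order matches :func:`_pack`: W1 rows, b1, W2, b2.
    """
    X = _as_2d(X)
    n = X.shape[0]
    a = X @ model.W1.T + model.b1          # (n, h)
    h = _sigmoid(a)
    z = h @ model.W2.ravel() + model.b2
    sp = h * (1.0 - h)                     # σ'(a)
    w2 = model.W2.ravel()
    # dz/dW1[j,k] = w2_j σ'(a_j) x_k ; dz/db1[j] = w2_j σ'(a_j)
    g = sp * w2                            # (n, h)
    dW1 = g[:, :, None] * X[:, None, :]    # (n, h, d)
    J = np.concatenate(
        [dW1.reshape(n, -1), g, h, np.ones((n, 1))], axis=1
    )
    return z, J


def lm_update(J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    """Solve the damped normal equations Δw = [JᵀJ + μI]⁻¹ Jᵀe."""
    JtJ = J.T @ J
    A = JtJ + mu * np.eye(JtJ.shape[0])
    return np.linalg.solve(A, J.T @ e)


@dataclass
class TrainConfig:
    """Levenberg–Marquardt training schedule.

    ``split`` fractions apply to a seeded per-sample shuffle; ``mu0`` is
    the initial damping with a ×``mu_up`` / ÷``mu_down`` schedule.
    """

    split: tuple = (0.70, 0.15, 0.15)
    mu0: float = 1e-3
    mu_up: float = 10.0
    mu_down: float = 10.0
    mu_max: float = 1e10
    max_epochs: int = 1000
    max_val_failures: int = 6
    grad_tol: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if len(self.split) != 3 or any(s < 0 for s in self.split):
            raise ParameterError("split must be three nonnegative fractions")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ParameterError("split fractions must sum to 1")
        if min(self.mu0, self.mu_up, self.mu_down, self.grad_tol) <= 0:
            raise ParameterError("mu0, mu_up, mu_down, grad_tol must be positive")
        if self.max_epochs < 1:
            raise ParameterError("max_epochs must be >= 1")


@dataclass
class TrainReport:
    """Per-epoch record of an LM run.

    ``train_sse`` holds the SSE after each accepted step (non-increasing by
    construction); ``val_sse`` the matching validation SSE.
    """

    train_sse: list = field(default_factory=list)
    val_sse: list = field(default_factory=list)
    stop_reason: str = ""
    final_mu: float = float("nan")
    epochs_run: int = 0
    best_val_epoch: int = -1


def split_indices(n: int, split: tuple, seed: int):
    """Seeded shuffle split into train/validation/test index arrays."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_tr = int(round(split[0] * n))
    n_va = int(round(split[1] * n))
    return idx[:n_tr], idx[n_tr : n_tr + n_va], idx[n_tr + n_va :]


def lm_train(model: MLPModel, X, y,
             cfg: Optional[TrainConfig] = None) -> tuple[MLPModel, TrainReport]:
    """Train the network on (features, normalized torque) pairs.

    Returns the model with the best-validation-epoch weights (final
    weights if the validation partition is empty) plus a
    :class:`TrainReport`.
    """
    if cfg is None:
        cfg = TrainConfig()
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ParameterError("feature rows and targets disagree in length")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise TrainingError("non-finite values in training data")
    min_rows = model.n_params + 1
    if X.shape[0] < min_rows:
        warnings.warn(
            f"dataset has {X.shape[0]} rows for {model.n_params} free "
            "parameters; the fit is underdetermined",
            stacklevel=2,
        )

    tr, va, _te = split_indices(X.shape[0], cfg.split, cfg.seed)
    Xtr, ytr = X[tr], y[tr]
    Xva, yva = X[va], y[va]

    w = _pack(model)
    mu = cfg.mu0
    report = TrainReport()
    best_val = np.inf
    best_w = w.copy()
    val_failures = 0
    prev_val = np.inf

    cur = _unpack(model, w)
    z, J = output_jacobian(cur, Xtr)
    e = ytr - z
    sse = float(e @ e)
    stop = ""
    epoch = 0
    while epoch < cfg.max_epochs:
        grad = J.T @ e
        if np.linalg.norm(grad, ord=np.inf) < cfg.grad_tol:
            stop = "grad_tol"
            break
        # inner damping loop: retry with larger mu until SSE decreases
        accepted = False
        while mu <= cfg.mu_max:
            dw = lm_update(J, e, mu)
            cand = _unpack(model, w + dw)
            z_new = forward(cand, Xtr)
            e_new = ytr - z_new
            sse_new = float(e_new @ e_new)
            if not np.isfinite(sse_new):
                raise TrainingError("training loss became non-finite")
            if sse_new < sse:
                accepted = True
                w = w + dw
                mu = mu / cfg.mu_down
                break
            mu = mu * cfg.mu_up
        if not accepted:
            stop = "mu_overflow"
            break
        epoch += 1
        cur = _unpack(model, w)
        z, J = output_jacobian(cur, Xtr)
        e = ytr - z
        sse = float(e @ e)
        report.train_sse.append(sse)
        if Xva.shape[0]:
            ev = yva - forward(cur, Xva)
            val = float(ev @ ev)
            report.val_sse.append(val)
            if val < best_val:
                best_val = val
                best_w = w.copy()
                report.best_val_epoch = epoch
            if val > prev_val:
                val_failures += 1
                if val_failures >= cfg.max_val_failures:
                    stop = "val_failures"
                    break
            else:
                val_failures = 0
            prev_val = val
        else:
            best_w = w.copy()
            report.best_val_epoch = epoch
    if not stop:
        stop = "max_epochs"
    report.stop_reason = stop
    report.final_mu = mu
    report.epochs_run = epoch
    trained = _unpack(model, best_w if np.isfinite(best_val) or not Xva.shape[0]
                      else w)
    trained.training_seed = cfg.seed
    return trained, report


# -- serialization -----------------------------------------------------------

def save_model(model: MLPModel, path) -> None:
    """Write the model as versioned JSON with full float precision."""
    payload = {
        "format": MODEL_FORMAT,
        "input_names": list(model.input_names),
        "hidden_n": model.hidden_n,
        "training_seed": model.training_seed,
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path) -> MLPModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelLoadError(f"{path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelLoadError(
            f"{path}: unsupported model format {payload.get('format')!r}"
            if isinstance(payload, dict)
            else f"{path}: model file is not a JSON object"
        )
    required = {"input_names", "hidden_n", "W1", "b1", "W2", "b2"}
    missing = required - set(payload)
    if missing:
        raise ModelLoadError(f"{path}: missing fields {sorted(missing)}")
    try:
        return MLPModel(
            input_names=tuple(payload["input_names"]),
            W1=np.array(payload["W1"], dtype=float),
            b1=np.array(payload["b1"], dtype=float),
            W2=np.array(payload["W2"], dtype=float),
            b2=payload["b2"],
            hidden_n=int(payload["hidden_n"]),
            training_seed=payload.get("training_seed"),
        )
    except (ParameterError, TypeError, ValueError) as exc:
        raise ModelLoadError(f"{path}: {exc}") from exc
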