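"""Model evaluation and fatigue statistics.

Covers four related analyses:

* agreement between predicted and measured normalized torque (Pearson r);
* timing accuracy at a torque-drop threshold — the time for each series to
  first fall to a fraction of its maximum, and the derived accuracy
  ``(1 − |t_pred − t_actual| / t_actual) × 100`` (not clamped: values
  below 0 flag gross failures rather than hiding them);
* the fatigue *critical point* — the breakpoint of the best continuous
  two-segment piecewise-linear fit to the predicted torque series,
  reported as a percentage of session duration;
* pre/post-drop gradient statistics and the paired two-tailed t-test
  battery used to compare model variants across standing sessions.

Torque-like series are smoothed with a moving average (default 5 s)
before threshold crossing, because raw first crossings are unstable on
noisy predictions; a window of 0 disables smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .errors import EvaluationError, InputError, ParameterError

#: Sentinel meaning a threshold was never crossed within the session.
NOT_REACHED = None

MODEL_VARIANTS = ("rms", "rms_zc")


def pearson_r(predicted, actual) -> float:
    """Pearson product-moment correlation between two series."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.size != y.size:
        raise ParameterError("series must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 points for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise EvaluationError("correlation undefined for zero-variance series")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def _smooth(series: np.ndarray, t: np.ndarray, smooth_s: float) -> np.ndarray:
    if smooth_s <= 0:
        return series
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    win = max(1, int(round(smooth_s / dt)))
    return uniform_filter1d(series, size=win, mode="nearest")


def time_to_fraction_drop(series_norm, t, fraction: float = 0.5,
                          smooth_s: float = 0.0):
    """Earliest time the (optionally smoothed) series falls to ``fraction``.

    ``series_norm`` must be max-normalized (maximum 1).  Returns the epoch
    time of the first sample ≤ ``fraction``, or :data:`NOT_REACHED` if the
    series never drops that far.
    """
    series = np.asarray(series_norm, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (0 < fraction < 1):
        raise ParameterError("fraction must lie in (0, 1)")
    if series.size != t.size or series.size == 0:
        raise ParameterError("series and t must be nonempty and equal length")
    if abs(series.max() - 1.0) > 1e-6:
        raise ParameterError(
            f"series is not max-normalized (max={series.max():.6g})"
        )
    smoothed = _smooth(series, t, smooth_s)
    below = np.nonzero(smoothed <= fraction)[0]
    if below.size == 0:
        return NOT_REACHED
    return float(t[below[0]])


def accuracy_pct(t_pred, t_actual):
    """Timing accuracy ``(1 − |t_pred − t_actual| / t_actual) × 100``.

    Unclamped; negative when the prediction misses by more than the actual
    time itself.  Returns None when either time is :data:`NOT_REACHED`.
    """
    if t_pred is NOT_REACHED or t_actual is NOT_REACHED:
        return None
    if t_actual <= 0:
        raise ParameterError("t_actual must be positive")
    return (1.0 - abs(t_pred - t_actual) / t_actual) * 100.0


@dataclass
class CriticalPoint:
    """Breakpoint of the two-segment piecewise-linear fit.

    ``time_norm`` is the breakpoint position as a percentage of session
    duration; ``torque_at_point`` the series value there; ``sse`` the
    total residual of the winning fit.  ``degenerate`` is set when a
    single line fits essentially as well as any hinge (no unique break).
    """

    time_norm: float
    torque_at_point: float
    sse: float
    t_break_s: float
    break_index: int
    degenerate: bool = False


#: Candidate breakpoints exclude this many epochs at each boundary.
_EDGE_EXCLUDE = 3


def _hinge_sse(t: np.ndarray, y: np.ndarray, tb: float) -> float:
    X = np.column_stack([np.ones(t.size), t, np.maximum(0.0, t - tb)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def detect_critical_point(pred_torque_norm, t) -> CriticalPoint:
    """Locate the gradient-change point of a predicted torque series.

    Fits a continuous two-segment ("hinge") linear model at every interior
    epoch, excluding the first and last 3, and returns the breakpoint that
    minimizes total SSE; exact ties go to the earliest candidate.
    """
    y = np.asarray(pred_torque_norm, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.size != t.size:
        raise ParameterError("series and t must have equal length")
    if y.size < 2 * _EDGE_EXCLUDE + 2:
        raise EvaluationError(
            f"critical-point detection needs at least {2 * _EDGE_EXCLUDE + 2} "
            f"epochs, got {y.size}"
        )
    best_idx = None
    best_sse = np.inf
    for b in range(_EDGE_EXCLUDE, y.size - _EDGE_EXCLUDE):
        sse = _hinge_sse(t, y, t[b])
        if best_idx is None or sse < best_sse - 1e-12 * max(1.0, best_sse):
            best_sse = sse
            best_idx = b
    # single straight line as degeneracy reference
    X = np.column_stack([np.ones(t.size), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    line_sse = float(r @ r)
    degenerate = (line_sse - best_sse) <= 1e-8 * max(line_sse, 1e-30)
    duration = float(t[-1])
    return CriticalPoint(
        time_norm=100.0 * float(t[best_idx]) / duration,
        torque_at_point=float(y[best_idx]),
        sse=best_sse,
        t_break_s=float(t[best_idx]),
        break_index=int(best_idx),
        degenerate=degenerate,
    )


def gradient_pre_post(series_norm, t, split_time: float,
                      window_s: Optional[float] = None):
    """Least-squares slopes on each side of ``split_time``.

    Slopes are in normalized units per second; each side needs at least 3
    epochs.  ``window_s`` restricts each side to that many seconds
    adjacent to the split (full side when None).
    """
    y = np.asarray(series_norm, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.size != t.size:
        raise ParameterError("series and t must have equal length")
    if not (t[0] < split_time < t[-1]):
        raise ParameterError("split_time must lie strictly inside the series")
    pre = t < split_time
    post = ~pre
    if window_s is not None:
        pre &= t >= split_time - window_s
        post &= t <= split_time + window_s
    if pre.sum() < 3 or post.sum() < 3:
        raise ParameterError("each side of the split needs at least 3 epochs")
    slope_pre = float(np.polyfit(t[pre], y[pre], 1)[0])
    slope_post = float(np.polyfit(t[post], y[post], 1)[0])
    return slope_pre, slope_post


def ttest_two_tailed(a, b, paired: bool = True) -> float:
    """Two-tailed t-test p-value (paired by default, Welch otherwise)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size and paired:
        raise ParameterError("paired test needs equal-length samples")
    if min(a.size, b.size) < 2:
        raise ParameterError("need at least 2 observations per sample")
    if paired:
        d = a - b
        if np.std(d) == 0:
            raise EvaluationError(
                "identical pairs: zero-variance differences leave the paired "
                "t-test undefined"
            )
        res = stats.ttest_rel(a, b)
    else:
        if np.std(a) == 0 and np.std(b) == 0:
            raise EvaluationError("zero variance in both samples")
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Extension-trial evaluation report


@dataclass
class EvaluationReport:
    """Per-trial agreement between predicted and actual normalized torque."""

    pearson_r: float
    t_actual_50: Optional[float]
    t_pred_50: Optional[float]
    accuracy_pct: Optional[float]
    drop_times_actual: dict
    drop_times_pred: dict
    negative_accuracy: bool = False

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "t_actual_50_s": self.t_actual_50,
            "t_pred_50_s": self.t_pred_50,
            "accuracy_pct": self.accuracy_pct,
            "drop_times_actual_s": self.drop_times_actual,
            "drop_times_pred_s": self.drop_times_pred,
            "negative_accuracy": self.negative_accuracy,
        }


DROP_FRACTIONS = (0.7, 0.5, 0.3)


def evaluate_prediction(predicted, actual_norm, t, drop: float = 0.5,
                        smooth_s: float = 5.0) -> EvaluationReport:
    """Score a predicted torque series against the measured one.

    Both series are max-normalized internally (predictions are unclipped
    network outputs).  Timing accuracy is evaluated at the ``drop``
    fraction; drop times at 70/50/30% are reported for both series.
    """
    pred = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual_norm, dtype=float)
    t = np.asarray(t, dtype=float)
    r = pearson_r(pred, actual)
    pred_n = pred / pred.max() if pred.max() > 0 else pred
    actual_n = actual / actual.max()
    t_act = time_to_fraction_drop(actual_n, t, drop, smooth_s)
    t_prd = time_to_fraction_drop(pred_n, t, drop, smooth_s)
    acc = accuracy_pct(t_prd, t_act)
    drops_a = {f: time_to_fraction_drop(actual_n, t, f, smooth_s)
               for f in DROP_FRACTIONS}
    drops_p = {f: time_to_fraction_drop(pred_n, t, f, smooth_s)
               for f in DROP_FRACTIONS}
    return EvaluationReport(
        pearson_r=r,
        t_actual_50=t_act,
        t_pred_50=t_prd,
        accuracy_pct=acc,
        drop_times_actual=drops_a,
        drop_times_pred=drops_p,
        negative_accuracy=(acc is not None and acc < 0),
    )


# ---------------------------------------------------------------------------
# Standing-session hypothesis battery


@dataclass
class StandingSession:
    """One evaluated standing session: features plus per-variant predictions.

    ``pred`` maps each model variant (``"rms"``, ``"rms_zc"``) to its
    predicted normalized-torque series over the same epoch grid ``t``.
    """

    label: str
    t: np.ndarray
    rms_norm: np.ndarray
    zc_norm: np.ndarray
    pred: dict

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.rms_norm = np.asarray(self.rms_norm, dtype=float)
        self.zc_norm = np.asarray(self.zc_norm, dtype=float)
        self.pred = {k: np.asarray(v, dtype=float) for k, v in self.pred.items()}


#: Number of epochs averaged for the "initial" and "final" torque levels.
_END_EPOCHS = 5


def _initial_final(series: np.ndarray):
    k = min(_END_EPOCHS, series.size)
    return float(np.mean(series[:k])), float(np.mean(series[-k:]))


def _fmt_p(a, b) -> str:
    try:
        return f"{ttest_two_tailed(a, b):.6g}"
    except EvaluationError:
        return "n/a"


def hypothesis_battery(sessions: Sequence[StandingSession],
                       smooth_s: float = 5.0):
    """Aggregate fatigue statistics across standing sessions.

    Produces two tables:

    * ``consistency`` — per-variant critical-point normalized time and
      predicted torque at the point (mean ± SD), with cross-variant paired
      t-tests;
    * ``hypotheses`` — per variant, four rows: initial vs final predicted
      torque, and pre- vs post-50%-drop gradients of RMS, ZC and the
      predicted torque, each with a paired two-tailed t-test across
      sessions.  p-values that are undefined (identical pairs) appear as
      ``"n/a"``.
    """
    sessions = list(sessions)
    if len(sessions) < 2:
        raise InputError("hypothesis battery needs at least 2 sessions")
    for s in sessions:
        missing = [m for m in MODEL_VARIANTS if m not in s.pred]
        if missing:
            raise InputError(
                f"session {s.label!r} lacks predictions for {missing}"
            )

    cp_time = {m: [] for m in MODEL_VARIANTS}
    cp_torque = {m: [] for m in MODEL_VARIANTS}
    init_t = {m: [] for m in MODEL_VARIANTS}
    final_t = {m: [] for m in MODEL_VARIANTS}
    grads = {m: {k: ([], []) for k in ("rms", "zc", "pred")}
             for m in MODEL_VARIANTS}
    for s in sessions:
        for m in MODEL_VARIANTS:
            p = s.pred[m]
            cp = detect_critical_point(p, s.t)
            cp_time[m].append(cp.time_norm)
            cp_torque[m].append(cp.torque_at_point)
            i0, i1 = _initial_final(p)
            init_t[m].append(i0)
            final_t[m].append(i1)
            pn = p / p.max() if p.max() > 0 else p
            t50 = time_to_fraction_drop(pn, s.t, 0.5, smooth_s)
            if t50 is NOT_REACHED or not (s.t[0] < t50 < s.t[-1]):
                continue
            for key, series in (("rms", s.rms_norm), ("zc", s.zc_norm),
                                ("pred", pn)):
                try:
                    pre, post = gradient_pre_post(series, s.t, t50)
                except ParameterError:
                    continue
                grads[m][key][0].append(pre)
                grads[m][key][1].append(post)

    consistency = pd.DataFrame(
        [
            {
                "quantity": "critical_time_norm_pct",
                "rms_mean": np.mean(cp_time["rms"]),
                "rms_sd": np.std(cp_time["rms"], ddof=1),
                "rms_zc_mean": np.mean(cp_time["rms_zc"]),
                "rms_zc_sd": np.std(cp_time["rms_zc"], ddof=1),
                "p_value": _fmt_p(cp_time["rms"], cp_time["rms_zc"]),
            },
            {
                "quantity": "critical_torque_norm",
                "rms_mean": np.mean(cp_torque["rms"]),
                "rms_sd": np.std(cp_torque["rms"], ddof=1),
                "rms_zc_mean": np.mean(cp_torque["rms_zc"]),
                "rms_zc_sd": np.std(cp_torque["rms_zc"], ddof=1),
                "p_value": _fmt_p(cp_torque["rms"], cp_torque["rms_zc"]),
            },
        ]
    )

    rows = []
    for m in MODEL_VARIANTS:
        rows.append({
            "model": m,
            "hypothesis": "initial_vs_final_torque",
            "pre_mean": np.mean(init_t[m]),
            "pre_sd": np.std(init_t[m], ddof=1),
            "post_mean": np.mean(final_t[m]),
            "post_sd": np.std(final_t[m], ddof=1),
            "p_value": _fmt_p(init_t[m], final_t[m]),
        })
        for key, name in (("rms", "rms_gradient_pre_post"),
                          ("zc", "zc_gradient_pre_post"),
                          ("pred", "pred_torque_gradient_pre_post")):
            pre, post = grads[m][key]
            if len(pre) >= 2:
                rows.append({
                    "model": m,
                    "hypothesis": name,
                    "pre_mean": np.mean(pre),
                    "pre_sd": np.std(pre, ddof=1),
                    "post_mean": np.mean(post),
                    "post_sd": np.std(post, ddof=1),
                    "p_value": _fmt_p(pre, post),
                })
            else:
                rows.append({
                    "model": m, "hypothesis": name,
                    "pre_mean": np.nan, "pre_sd": np.nan,
                    "post_mean": np.nan, "post_sd": np.nan,
                    "p_value": "n/a",
                })
    hypotheses = pd.DataFrame(rows)
    return {"consistency": consistency, "hypotheses": hypotheses}
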