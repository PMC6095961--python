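"""Synthetic FES-fatigue sessions with ground-truth labels.

Emulates the signal structure of electrically evoked quadriceps
contractions recorded to fatigue:

* normalized torque holds a plateau near 1, then declines along a
  logistic toward a floor (fatigue), crossing 50% of maximum at a known
  time ``t_50_s``;
* the MMG is band-limited Gaussian noise whose envelope tracks torque
  (amplitude ∝ force), so per-epoch RMS follows the torque decline;
* past the 50% torque drop the carrier band centre shifts upward
  (slow-to-fast fibre recruitment), so the per-epoch zero-crossing rate
  rises sharply late in the session;
* in standing mode the knee angle stays extended while torque is above
  50% of maximum, then flexes toward the 30° buckle that ends the
  session; an optional buckle artifact ramps the MMG envelope up at the
  end of standing sessions.

The generator is purely phenomenological — it reproduces the feature-
level behaviour needed to exercise the estimation pipeline, not muscle
electrophysiology.  All randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.signal import butter, sosfilt

from .errors import ParameterError
from .signal_io import RawRecording, write_channel

#: Knee angle (degrees) at which a standing session ends.
BUCKLE_ANGLE_DEG = 30.0

#: Normalized-torque margin above the floor at which the knee reaches the
#: buckle angle; keeps the buckle time finite on an asymptotic decline.
ANGLE_FLOOR_MARGIN = 0.02


@dataclass
class BuckleParams:
    """End-of-session MMG amplitude surge seen at knee buckling.

    Disabled by default: the surge is a mechanical disturbance of the
    standing posture, not part of the muscle-fatigue signal itself.
    """

    enabled: bool = False
    start_frac: float = 0.85
    amplitude_gain: float = 2.0


@dataclass
class FatigueModelParams:
    """Generator parameters for one session.

    Defaults describe a stimulation session of a few minutes whose torque
    declines from a plateau to ~30% of maximum, with MMG envelope gain
    and noise chosen to give a clearly fatiguing but realistically noisy
    trace.
    """

    duration_s: float = 300.0
    fs_mmg: float = 1000.0
    fs_torque: float = 500.0
    torque_max: float = 35.0          # N·m, plateau torque
    t_onset_s: float = 60.0           # decline onset: T(t_onset) = 0.95
    decay_rate: float = 0.045         # logistic rate, 1/s
    torque_floor_frac: float = 0.3    # asymptotic normalized torque
    rms_gain: float = 0.2             # MMG envelope volts per unit T
    rms_offset: float = 0.02          # envelope at zero torque
    band_lo_pre: float = 40.0         # carrier band before 50% drop, Hz
    band_hi_pre: float = 80.0
    band_lo_post: float = 80.0        # carrier band after 50% drop, Hz
    band_hi_post: float = 160.0
    crossfade_s: float = 10.0         # band transition width
    noise_sd: float = 0.01            # white measurement noise, volts
    torque_noise_sd: float = 0.5      # dynamometer noise, N·m
    stim_freq_hz: float = 30.0        # metadata tag only
    buckle: BuckleParams = field(default_factory=BuckleParams)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.buckle, dict):
            self.buckle = BuckleParams(**self.buckle)
        if self.duration_s <= 0 or self.fs_mmg <= 0 or self.fs_torque <= 0:
            raise ParameterError("duration and sampling rates must be positive")
        if not (0 <= self.torque_floor_frac < 1):
            raise ParameterError("torque_floor_frac must lie in [0, 1)")
        for lo, hi in ((self.band_lo_pre, self.band_hi_pre),
                       (self.band_lo_post, self.band_hi_post)):
            if not (20.0 <= lo < hi <= 200.0):
                raise ParameterError(
                    "carrier bands must lie inside the 20-200 Hz MMG band"
                )
        if min(self.decay_rate, self.rms_gain, self.torque_max) <= 0:
            raise ParameterError("rates and gains must be positive")
        if self.t_onset_s < 0:
            raise ParameterError("t_onset_s must be nonnegative")


def _t_mid(params: FatigueModelParams) -> float:
    # placement of the logistic midpoint so that T(t_onset) = 0.95
    f = params.torque_floor_frac
    if f >= 0.95:
        raise ParameterError("torque_floor_frac must be below 0.95")
    return params.t_onset_s - np.log(0.05 / (0.95 - f)) / params.decay_rate


def torque_at(t, params: FatigueModelParams) -> np.ndarray:
    """Normalized torque T(t) = floor + (1 − floor) / (1 + exp(r (t − t_mid)))."""
    t = np.asarray(t, dtype=float)
    f = params.torque_floor_frac
    return f + (1.0 - f) / (1.0 + np.exp(params.decay_rate * (t - _t_mid(params))))


def crossing_time(params: FatigueModelParams, level: float = 0.5):
    """Analytic time at which T(t) first reaches ``level`` (None if never)."""
    f = params.torque_floor_frac
    if level <= f or level >= 1.0:
        return None
    t = _t_mid(params) + np.log((1.0 - f) / (level - f) - 1.0) / params.decay_rate
    if t < 0 or t > params.duration_s:
        return None
    return float(t)


@dataclass
class TorqueProfile:
    """Sampled normalized torque trace with its analytic crossing times."""

    t: np.ndarray
    values: np.ndarray
    t_50_s: Optional[float]
    t_mid_s: float


def simulate_torque_profile(params: FatigueModelParams,
                            fs: Optional[float] = None) -> TorqueProfile:
    """Deterministic normalized torque trace (no noise) at rate ``fs``."""
    fs = params.fs_torque if fs is None else fs
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    return TorqueProfile(
        t=t,
        values=torque_at(t, params),
        t_50_s=crossing_time(params, 0.5),
        t_mid_s=_t_mid(params),
    )


def _unit_band_noise(n: int, fs: float, lo: float, hi: float,
                     rng: np.random.Generator) -> np.ndarray:
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_mmg(torque_norm, params: FatigueModelParams,
                 mode: str = "extension",
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Raw MMG trace for a per-MMG-sample normalized torque trace.

    The carrier crossfades from the pre-fatigue band to the post-drop band
    over ``crossfade_s`` seconds starting at the 50% torque crossing; the
    envelope is ``rms_offset + rms_gain * T(t)`` plus white measurement
    noise.  In standing mode with the buckle artifact enabled the
    envelope is additionally ramped up from ``start_frac`` of the session
    to its end.
    """
    T = np.asarray(torque_norm, dtype=float)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = T.size
    fs = params.fs_mmg
    t = np.arange(n) / fs
    pre = _unit_band_noise(n, fs, params.band_lo_pre, params.band_hi_pre, rng)
    post = _unit_band_noise(n, fs, params.band_lo_post, params.band_hi_post, rng)
    t50 = crossing_time(params, 0.5)
    if t50 is None:
        w = np.zeros(n)
    else:
        w = np.clip((t - t50) / params.crossfade_s, 0.0, 1.0)
    carrier = (1.0 - w) * pre + w * post
    # keep unit variance through the crossfade of two independent noises
    carrier /= np.sqrt((1.0 - w) ** 2 + w ** 2)
    env = params.rms_offset + params.rms_gain * T
    if mode == "standing" and params.buckle.enabled:
        dur = t[-1] if n else 0.0
        t0 = params.buckle.start_frac * dur
        if dur > t0:
            ramp = 1.0 + (params.buckle.amplitude_gain - 1.0) * np.clip(
                (t - t0) / (dur - t0), 0.0, 1.0
            )
            env = env * ramp
    return env * carrier + rng.normal(0.0, params.noise_sd, n)


def simulate_knee_angle(torque_norm, params: FatigueModelParams) -> np.ndarray:
    """Knee flexion angle (degrees) for a normalized torque trace.

    0° (fully extended) while T ≥ 0.5; flexes linearly in T toward the
    30° buckle angle, reached when T falls to the floor plus a small
    margin.  Nondecreasing because T is nonincreasing.
    """
    T = np.asarray(torque_norm, dtype=float)
    lo = params.torque_floor_frac + ANGLE_FLOOR_MARGIN
    if lo >= 0.5:
        raise ParameterError(
            "torque_floor_frac too high for a standing session: the knee "
            "angle mapping needs floor + margin < 0.5"
        )
    frac = np.clip((0.5 - T) / (0.5 - lo), 0.0, 1.0)
    return BUCKLE_ANGLE_DEG * frac


@dataclass
class SyntheticSession:
    """One generated session plus its ground truth.

    ``truth`` holds ``t_50_s`` (analytic time normalized torque crosses
    0.5, None if never), ``t_onset_s`` (decline onset), and
    ``torque_norm_per_epoch`` (true per-1-s-epoch mean normalized torque).
    Standing sessions carry a knee-angle trace instead of a torque
    channel; their true torque lives only in ``truth``.
    """

    recording: RawRecording
    params: FatigueModelParams
    truth: dict
    knee_angle: Optional[np.ndarray] = None
    fs_angle: float = 1000.0


def _epoch_means(values: np.ndarray, per: int) -> np.ndarray:
    n = values.size // per
    return values[: n * per].reshape(n, per).mean(axis=1)


def _gradient_change_time(T_epoch: np.ndarray, epoch_s: float = 1.0):
    """Ground-truth change point: hinge breakpoint of the noiseless profile.

    The label a gradient-change detector should recover is where the true
    torque profile's piecewise-linear gradient changes, found by the same
    exhaustive two-segment SSE search used downstream but applied to the
    noiseless per-epoch torque.  None when the profile has no usable break
    (flat, or too short).
    """
    from .evaluation import EvaluationError, detect_critical_point

    t = np.arange(1, T_epoch.size + 1) * epoch_s
    try:
        cp = detect_critical_point(T_epoch, t)
    except EvaluationError:
        return None
    if cp.degenerate:
        return None
    return cp.t_break_s


def simulate_session(params: FatigueModelParams,
                     mode: str = "extension") -> SyntheticSession:
    """Generate one complete session in the given mode."""
    if mode not in ("extension", "standing"):
        raise ParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(params.seed)
    fs = params.fs_mmg
    n_mmg = int(round(params.duration_s * fs))
    t_mmg = np.arange(n_mmg) / fs
    T_mmg = torque_at(t_mmg, params)

    if mode == "standing":
        theta = simulate_knee_angle(T_mmg, params)
        hit = np.nonzero(theta >= BUCKLE_ANGLE_DEG)[0]
        if hit.size:
            # truncate to whole seconds so epochs stay aligned
            end_s = max(1.0, np.floor(t_mmg[hit[0]]))
        else:
            end_s = params.duration_s
        n_mmg = int(round(end_s * fs))
        t_mmg = t_mmg[:n_mmg]
        T_mmg = T_mmg[:n_mmg]
        theta = theta[:n_mmg]
        mmg = simulate_mmg(T_mmg, params, mode="standing", rng=rng)
        recording = RawRecording(
            mmg=mmg, fs_mmg=fs, torque=None, fs_torque=params.fs_torque,
            label=f"standing-seed{params.seed}", mode="standing",
        )
        T_epoch = _epoch_means(T_mmg, int(round(fs)))
        truth = {
            "t_50_s": crossing_time(params, 0.5),
            "t_onset_s": params.t_onset_s,
            "t_gradient_change_s": _gradient_change_time(T_epoch),
            "duration_s": float(end_s),
            "torque_norm_per_epoch": T_epoch.tolist(),
        }
        return SyntheticSession(
            recording=recording, params=params, truth=truth,
            knee_angle=theta, fs_angle=fs,
        )

    mmg = simulate_mmg(T_mmg, params, mode="extension", rng=rng)
    n_tq = int(round(params.duration_s * params.fs_torque))
    t_tq = np.arange(n_tq) / params.fs_torque
    torque = params.torque_max * torque_at(t_tq, params)
    torque = torque + rng.normal(0.0, params.torque_noise_sd, n_tq)
    np.clip(torque, 0.0, None, out=torque)
    recording = RawRecording(
        mmg=mmg, fs_mmg=fs, torque=torque, fs_torque=params.fs_torque,
        label=f"extension-seed{params.seed}", mode="extension",
    )
    T_epoch = _epoch_means(T_mmg, int(round(fs)))
    truth = {
        "t_50_s": crossing_time(params, 0.5),
        "t_onset_s": params.t_onset_s,
        "t_gradient_change_s": _gradient_change_time(T_epoch),
        "duration_s": float(params.duration_s),
        "torque_norm_per_epoch": T_epoch.tolist(),
    }
    return SyntheticSession(recording=recording, params=params, truth=truth)


# ---------------------------------------------------------------------------
# Cohorts

#: Per-session uniform sampling ranges for cohort generation.  Spans the
#: qualitative variation seen across stimulation sessions: onset and speed
#: of the decline, residual torque, absolute torque level and signal
#: quality.
DEFAULT_PARAM_RANGES = {
    "t_onset_s": (40.0, 80.0),
    "decay_rate": (0.03, 0.06),
    "torque_floor_frac": (0.25, 0.35),
    "torque_max": (25.0, 45.0),
    "rms_gain": (0.18, 0.22),
    "noise_sd": (0.008, 0.012),
}


def sample_params(rng: np.random.Generator, mode: str = "extension",
                  params_ranges: Optional[dict] = None,
                  **overrides) -> FatigueModelParams:
    """Draw one session's parameters from uniform ranges."""
    ranges = dict(DEFAULT_PARAM_RANGES if params_ranges is None
                  else params_ranges)
    fields = set(FatigueModelParams.__dataclass_fields__)
    kwargs = {}
    for name, bounds in ranges.items():
        if name not in fields:
            raise ParameterError(f"unknown parameter {name!r} in ranges")
        lo, hi = bounds
        if hi < lo:
            raise ParameterError(f"invalid range for {name!r}: ({lo}, {hi})")
        kwargs[name] = float(rng.uniform(lo, hi))
    kwargs["seed"] = int(rng.integers(0, 2 ** 31 - 1))
    kwargs.update(overrides)
    return FatigueModelParams(**kwargs)


def generate_cohort(n_sessions: int, mode: str = "extension",
                    params_ranges: Optional[dict] = None, seed: int = 0,
                    out_dir=None, **overrides) -> list:
    """Generate a cohort of independent sessions from a master seed.

    Each session's parameters are drawn from ``params_ranges`` (defaults
    to :data:`DEFAULT_PARAM_RANGES`) with its own derived seed, so the
    whole cohort is reproducible from ``seed`` alone.  When ``out_dir``
    is given, each session is written to ``session_XX/`` as channel CSVs
    plus ``truth.json`` and ``params.yaml``, with a cohort-level
    ``manifest.yaml``.
    """
    if n_sessions < 1:
        raise ParameterError("n_sessions must be >= 1")
    rng = np.random.default_rng(seed)
    sessions = []
    for _ in range(n_sessions):
        params = sample_params(rng, mode=mode, params_ranges=params_ranges,
                               **overrides)
        sessions.append(simulate_session(params, mode=mode))
    if out_dir is not None:
        write_cohort(sessions, out_dir)
    return sessions


def write_cohort(sessions, out_dir) -> None:
    """Write session directories plus a cohort manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(sessions):
        d = out / f"session_{i:02d}"
        d.mkdir(exist_ok=True)
        write_channel(s.recording.mmg, s.recording.fs_mmg, d / "mmg.csv")
        entry = {
            "dir": d.name,
            "mode": s.recording.mode,
            "label": s.recording.label,
            "fs_mmg": s.recording.fs_mmg,
        }
        if s.recording.torque is not None:
            write_channel(s.recording.torque, s.recording.fs_torque,
                          d / "torque.csv")
            entry["fs_torque"] = s.recording.fs_torque
        if s.knee_angle is not None:
            write_channel(s.knee_angle, s.fs_angle, d / "knee_angle.csv")
            entry["fs_angle"] = s.fs_angle
        with open(d / "truth.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(s.truth, fh, indent=1)
            fh.write("\n")
        with open(d / "params.yaml", "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(asdict(s.params), fh, sort_keys=True)
        entries.append(entry)
    with open(out / "manifest.yaml", "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump({"sessions": entries}, fh, sort_keys=False)
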