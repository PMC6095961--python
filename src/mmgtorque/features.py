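"""MMG feature extraction: band-pass filtering, per-epoch RMS and zero
crossings, and 0–1 normalization.

The two features are the classic surface-MMG amplitude and frequency
surrogates:

* RMS of each 1-s segment, ``sqrt(mean(x_k^2))`` — tracks contractile
  force via the mechanical vibration amplitude.
* Zero crossings, the number of strict sign alternations in the segment —
  a spectral surrogate that rises with contraction frequency without
  requiring an FFT.  A zero-valued sample contributes no crossing (the
  sign function of a zero product is taken as 0), which is the convention
  used throughout this package.

Both feature series and the per-epoch mean torque are scaled by their
per-trial maximum so that every series lives in [0, 1] with its maximum at
1; the divisor is retained so physical units can be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import FormatError, NormalizationError, ParameterError
from .signal_io import RawRecording, epoch_align

FEATURE_COLUMNS = [
    "epoch_s",
    "rms",
    "zc",
    "torque_mean",
    "rms_norm",
    "zc_norm",
    "torque_norm",
]


def bandpass(raw, fs: float, lo_hz: float = 20.0, hi_hz: float = 200.0,
             order: int = 4):
    """Zero-phase Butterworth band-pass filter.

    A 4th-order Butterworth is applied forward-backward (``sosfiltfilt``) so
    the filter adds no phase distortion at epoch boundaries.  Passband
    frequencies are attenuated by < 1 dB in steady state; frequencies far
    outside the band by > 20 dB.
    """
    raw = np.asarray(raw, dtype=float)
    if not (0 < lo_hz < hi_hz):
        raise ParameterError("need 0 < lo_hz < hi_hz")
    if hi_hz >= fs / 2:
        raise ParameterError(
            f"hi_hz={hi_hz} must be below the Nyquist frequency {fs / 2}"
        )
    if raw.size == 0:
        return raw.copy()
    sos = butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, raw)


def rms_epoch(segment) -> float:
    """Root mean square of one segment: ``sqrt((1/N) * sum(x_k^2))``."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ParameterError("rms_epoch requires at least one sample")
    if not np.all(np.isfinite(segment)):
        raise ParameterError("segment contains non-finite samples")
    return float(np.sqrt(np.mean(segment ** 2)))


def zc_epoch(segment) -> int:
    """Count strict sign alternations in one segment.

    Implements ``sum_k sgn(-x_k * x_{k+1})`` with ``sgn(x) = 1`` if
    ``x > 0`` else 0: only adjacent pairs with strictly opposite signs
    count, so a zero sample yields no crossing.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ParameterError("zc_epoch requires at least two samples")
    return int(np.count_nonzero(segment[:-1] * segment[1:] < 0))


@dataclass
class NormalizedSeries:
    """A nonnegative series divided by its maximum.

    ``values`` lie in [0, 1] with max exactly 1; ``scale_max`` is the
    pre-normalization maximum, kept so ``denormalize`` is lossless.
    """

    values: np.ndarray
    scale_max: float

    def denormalize(self) -> np.ndarray:
        return self.values * self.scale_max


def normalize_max(series) -> NormalizedSeries:
    """Scale a nonnegative series to [0, 1] by its maximum."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise NormalizationError("cannot normalize an empty series")
    if np.any(series < 0):
        raise NormalizationError(
            f"series contains negative values (min={series.min():.3g}); "
            "max-normalization requires nonnegative input"
        )
    m = float(series.max())
    if m <= 0:
        raise NormalizationError("series maximum is zero; nothing to scale by")
    return NormalizedSeries(values=series / m, scale_max=m)


@dataclass
class EpochFeatureSeries:
    """Time-aligned per-epoch features.

    Attributes
    ----------
    t
        Epoch end-times in seconds (1-based epochs: first epoch ends at
        ``epoch_s``).
    rms
        Per-epoch MMG RMS in signal units.
    zc
        Per-epoch zero-crossing counts.
    torque
        Per-epoch mean torque in N·m, or None for torque-less (standing)
        recordings.
    """

    t: np.ndarray
    rms: np.ndarray
    zc: np.ndarray
    torque: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.rms = np.asarray(self.rms, dtype=float)
        self.zc = np.asarray(self.zc, dtype=int)
        if self.torque is not None:
            self.torque = np.asarray(self.torque, dtype=float)
        n = self.t.size
        for name in ("rms", "zc", "torque"):
            arr = getattr(self, name)
            if arr is not None and arr.size != n:
                raise ParameterError(f"{name} length {arr.size} != t length {n}")
        if np.any(self.rms < 0):
            raise ParameterError("rms must be nonnegative")
        if np.any(self.zc < 0):
            raise ParameterError("zc must be nonnegative")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        """Feature table with raw and max-normalized columns."""
        df = pd.DataFrame({"epoch_s": self.t, "rms": self.rms, "zc": self.zc})
        df["torque_mean"] = self.torque if self.torque is not None else np.nan
        df["rms_norm"] = _safe_norm(self.rms)
        df["zc_norm"] = _safe_norm(self.zc.astype(float))
        df["torque_norm"] = (
            _safe_norm(self.torque) if self.torque is not None else np.nan
        )
        return df[FEATURE_COLUMNS]

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def _safe_norm(series: np.ndarray) -> np.ndarray:
    """Max-normalize, passing an all-zero series through unchanged."""
    m = float(np.max(series)) if series.size else 0.0
    return series / m if m > 0 else np.asarray(series, dtype=float)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV written by :meth:`EpochFeatureSeries.write_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: feature table missing columns {missing}")
    return df


def extract_features(recording: RawRecording, epoch_s: float = 1.0,
                     band=(20.0, 200.0)) -> EpochFeatureSeries:
    """Full feature pipeline: band-pass, epoch, RMS + ZC per epoch.

    Torque means are attached when the recording carries a torque channel.
    """
    filtered = bandpass(recording.mmg, recording.fs_mmg, band[0], band[1])
    aligned = epoch_align(
        RawRecording(
            mmg=filtered,
            fs_mmg=recording.fs_mmg,
            torque=recording.torque,
            fs_torque=recording.fs_torque,
            label=recording.label,
            mode=recording.mode,
        ),
        epoch_s=epoch_s,
    )
    n = len(aligned)
    t = (np.arange(1, n + 1)) * epoch_s
    rms = np.array([rms_epoch(seg) for seg, _ in aligned]) if n else np.empty(0)
    zc = np.array([zc_epoch(seg) for seg, _ in aligned], dtype=int) if n else np.empty(0, int)
    torque = None
    if recording.torque is not None:
        torque = np.array([tq for _, tq in aligned]) if n else np.empty(0)
    return EpochFeatureSeries(t=t, rms=rms, zc=zc, torque=torque)
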