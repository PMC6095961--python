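"""Channel-file I/O and MMG/torque epoch synchronization.

A *channel file* is a two-column CSV (``time_s,value``) carrying one
uniformly sampled signal with explicit time stamps.  The declared sampling
rate is always validated against the stamps rather than inferred, so a
mislabelled recording fails loudly instead of silently shifting every
epoch.

A :class:`RawRecording` bundles the single-channel MMG trace (typically
1 kHz) with the optional dynamometer torque trace (typically 500 Hz).
:func:`epoch_align` cuts both into common 1-second epochs: epoch *i*
(1-based) covers MMG samples ``[(i-1)*fs_mmg*epoch_s, i*fs_mmg*epoch_s)``
and the torque mean over the matching torque-sample window.  A trailing
partial epoch is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import (
    ChannelParseError,
    FormatError,
    MetadataError,
    ParameterError,
)

CHANNEL_HEADER = "time_s,value"

#: Maximum tolerated deviation (seconds) between a time stamp and its
#: nominal position ``index / fs``.
TIME_TOL_S = 1e-9

MODES = ("extension", "standing")


@dataclass
class RawRecording:
    """A raw MMG trace with optional synchronized torque.

    Parameters
    ----------
    mmg
        Raw MMG samples (volts, arbitrary gain).
    fs_mmg
        MMG sampling rate in samples/s.
    torque
        Optional dynamometer torque samples (N·m).
    fs_torque
        Torque sampling rate in samples/s.
    label
        Trial identifier.
    mode
        ``"extension"`` (seated isometric, torque available) or
        ``"standing"`` (no torque channel).
    """

    mmg: np.ndarray
    fs_mmg: float = 1000.0
    torque: Optional[np.ndarray] = None
    fs_torque: float = 500.0
    label: str = ""
    mode: str = "extension"

    def __post_init__(self):
        self.mmg = np.asarray(self.mmg, dtype=float)
        if self.fs_mmg <= 0 or self.fs_torque <= 0:
            raise ParameterError("sampling rates must be positive")
        if self.mmg.ndim != 1:
            raise ParameterError("mmg must be a 1-D sample array")
        if self.mmg.size and not np.all(np.isfinite(self.mmg)):
            raise ParameterError("mmg contains non-finite samples")
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.torque is not None:
            self.torque = np.asarray(self.torque, dtype=float)
            if self.torque.ndim != 1:
                raise ParameterError("torque must be a 1-D sample array")
            if self.torque.size and not np.all(np.isfinite(self.torque)):
                raise ParameterError("torque contains non-finite samples")
            # Durations must agree to within one epoch (1 s): anything worse
            # indicates a sync or metadata fault upstream.
            d_mmg = self.mmg.size / self.fs_mmg
            d_tq = self.torque.size / self.fs_torque
            if abs(d_mmg - d_tq) > 1.0:
                raise MetadataError(
                    f"MMG duration {d_mmg:.3f}s and torque duration {d_tq:.3f}s "
                    "differ by more than one epoch"
                )

    @property
    def duration_s(self) -> float:
        """Common duration of the recording in seconds."""
        d = self.mmg.size / self.fs_mmg
        if self.torque is not None:
            d = min(d, self.torque.size / self.fs_torque)
        return d


def write_channel(samples, fs: float, path) -> None:
    """Write a channel file with ``time_s = index / fs`` starting at 0.

    Values and times are written with ``repr`` (shortest round-trip float
    form) so that ``read_channel`` reproduces them bit-identically.
    """
    samples = np.asarray(samples, dtype=float)
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if samples.size and not np.all(np.isfinite(samples)):
        raise ParameterError("samples contain non-finite values")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(CHANNEL_HEADER + "\n")
        for i, v in enumerate(samples):
            fh.write(f"{i / fs!r},{float(v)!r}\n")


def read_channel(path, expected_fs: float) -> np.ndarray:
    """Read a channel file, validating the declared sampling rate.

    Raises
    ------
    FormatError
        Missing or wrong header.
    ChannelParseError
        Non-numeric row (carries the 1-based line number).
    MetadataError
        Time stamps inconsistent with ``expected_fs``.
    """
    if expected_fs <= 0:
        raise ParameterError("expected_fs must be positive")
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n")
        if header != CHANNEL_HEADER:
            raise FormatError(
                f"{path}: expected header {CHANNEL_HEADER!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ChannelParseError(f"expected 2 fields, got {len(parts)}", lineno)
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ChannelParseError(str(exc), lineno) from exc
    t = np.asarray(times)
    if t.size:
        nominal = np.arange(t.size) / expected_fs + t[0]
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise MetadataError(f"{path}: time_s is not strictly increasing")
        dev = np.max(np.abs(t - nominal))
        if dev > max(TIME_TOL_S, 4 * np.abs(t[-1]) * np.finfo(float).eps):
            raise MetadataError(
                f"{path}: time stamps deviate from fs={expected_fs} "
                f"by up to {dev:.3g}s"
            )
    return np.asarray(values, dtype=float)


def _samples_per_epoch(fs: float, epoch_s: float) -> int:
    n = fs * epoch_s
    n_int = int(round(n))
    if n_int < 1 or abs(n - n_int) > 1e-9:
        raise ParameterError(
            f"epoch of {epoch_s}s does not hold an integer number of samples at fs={fs}"
        )
    return n_int


def epoch_align(recording: RawRecording, epoch_s: float = 1.0):
    """Cut a recording into fixed-length epochs.

    Returns a list of ``(mmg_segment, mean_torque_or_None)`` tuples, one per
    complete epoch.  The number of epochs is ``floor(duration / epoch_s)``
    over the common duration; a recording shorter than one epoch yields an
    empty list.  MMG segmentation does not depend on torque presence.
    """
    if epoch_s <= 0:
        raise ParameterError("epoch_s must be positive")
    spm = _samples_per_epoch(recording.fs_mmg, epoch_s)
    n_epochs = recording.mmg.size // spm
    if recording.torque is not None:
        spt = _samples_per_epoch(recording.fs_torque, epoch_s)
        n_epochs = min(n_epochs, recording.torque.size // spt)
    out = []
    for i in range(n_epochs):
        seg = recording.mmg[i * spm : (i + 1) * spm]
        if recording.torque is not None:
            tq = float(np.mean(recording.torque[i * spt : (i + 1) * spt]))
        else:
            tq = None
        out.append((seg, tq))
    return out


# ---------------------------------------------------------------------------
# Trial manifest


@dataclass
class TrialManifest:
    """Paths and metadata for one recorded trial.

    ``mmg_start_offset_s`` handles the acquisition convention in which the
    MMG recorder is started slightly before stimulation/torque recording:
    that many seconds are dropped from the head of the MMG trace on load.
    """

    mmg_path: str
    torque_path: Optional[str] = None
    fs_mmg: float = 1000.0
    fs_torque: float = 500.0
    label: str = ""
    mode: str = "extension"
    mmg_start_offset_s: float = 0.0


def load_manifest(path) -> TrialManifest:
    """Read a YAML trial manifest."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "mmg_path" not in raw:
        raise FormatError(f"{path}: manifest must be a mapping with an 'mmg_path' key")
    known = set(TrialManifest.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown manifest keys {sorted(unknown)}")
    return TrialManifest(**raw)


def load_recording(manifest: TrialManifest, base_dir=None) -> RawRecording:
    """Load the channels named by a manifest into a :class:`RawRecording`."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    mmg = read_channel(base / manifest.mmg_path, manifest.fs_mmg)
    if manifest.mmg_start_offset_s:
        if manifest.mmg_start_offset_s < 0:
            raise ParameterError("mmg_start_offset_s must be >= 0")
        skip = int(round(manifest.mmg_start_offset_s * manifest.fs_mmg))
        mmg = mmg[skip:]
    torque = None
    if manifest.torque_path is not None:
        torque = read_channel(base / manifest.torque_path, manifest.fs_torque)
    return RawRecording(
        mmg=mmg,
        fs_mmg=manifest.fs_mmg,
        torque=torque,
        fs_torque=manifest.fs_torque,
        label=manifest.label,
        mode=manifest.mode,
    )
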