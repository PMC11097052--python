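"""Shared signal transforms.

All filters are zero-phase (forward-backward Butterworth) so detected event
times are not systematically shifted.  Acceleration is in g; thresholds
throughout the package are therefore g-scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Recording

__all__ = [
    "FilterSpec",
    "apply_filter",
    "accel_norm",
    "estimate_vertical",
    "moving_stat",
    "activity_counts",
    "resample_to",
]


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter specification applied zero-phase."""

    kind: str  # "lowpass" | "highpass" | "bandpass"
    cutoff_hz: float | tuple[float, float]
    order: int = 4

    def __post_init__(self):
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        cutoffs = np.atleast_1d(np.asarray(self.cutoff_hz, dtype=float))
        if np.any(cutoffs <= 0):
            raise ValueError("cutoffs must be > 0")
        if self.kind == "bandpass" and cutoffs.size != 2:
            raise ValueError("bandpass needs two cutoffs")


def apply_filter(series: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase filtering along the first axis."""
    cutoffs = np.atleast_1d(np.asarray(spec.cutoff_hz, dtype=float))
    if np.any(cutoffs >= fs / 2):
        raise ValueError(f"cutoff {spec.cutoff_hz} at or above Nyquist for fs={fs}")
    wn = cutoffs if cutoffs.size > 1 else float(cutoffs[0])
    sos = signal.butter(spec.order, wn, btype=spec.kind, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=0)


def accel_norm(recording: Recording) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes, in g.

    Rotation invariant, which is why every axis-specific dependency in the
    detectors is replaced by this signal.
    """
    return np.linalg.norm(recording.acc, axis=1)


def estimate_vertical(recording: Recording, gravity_cutoff_hz: float = 0.25) -> np.ndarray:
    """Per-sample projection of acceleration onto the low-pass gravity direction.

    The gravity direction is estimated with a zero-phase low-pass at
    ``gravity_cutoff_hz``; the raw signal is then projected onto the unit
    gravity vector sample by sample.  Requires at least ``4 / cutoff``
    seconds of data for a stable estimate.
    """
    if recording.duration_s <= 4.0 / gravity_cutoff_hz:
        raise ValueError(
            f"recording too short ({recording.duration_s:.1f} s) for gravity "
            f"cutoff {gravity_cutoff_hz} Hz"
        )
    grav = apply_filter(
        recording.acc, FilterSpec("lowpass", gravity_cutoff_hz, order=2), recording.fs
    )
    norms = np.linalg.norm(grav, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = grav / norms
    return np.sum(recording.acc * unit, axis=1)


def moving_stat(series: np.ndarray, window_s: float, stat: str, fs: float) -> np.ndarray:
    """Centered moving statistic with shrinking windows at the edges.

    ``stat`` is one of ``mean``, ``sd`` (population SD) or ``rms``.
    Output has the same length as the input.
    """
    if stat not in ("mean", "sd", "rms"):
        raise ValueError(f"unknown stat {stat!r}")
    x = np.asarray(series, dtype=float)
    w = max(int(round(window_s * fs)), 1)
    half = w // 2
    n = x.size
    # work on the mean-shifted signal so constant series give exact zeros
    mu = x.mean()
    y = x - mu
    cs = np.concatenate([[0.0], np.cumsum(y)])
    cs2 = np.concatenate([[0.0], np.cumsum(y * y)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (w - half), n)
    cnt = hi - lo
    mean = (cs[hi] - cs[lo]) / cnt + mu
    if stat == "mean":
        return mean
    msq = (cs2[hi] - cs2[lo]) / cnt
    var = np.maximum(msq - ((cs[hi] - cs[lo]) / cnt) ** 2, 0.0)
    if stat == "sd":
        return np.sqrt(var)
    return np.sqrt(var + mean**2)  # rms


# Open reconstruction of proprietary actigraphy counts: band-pass, rectify,
# dead-band, saturate, accumulate.  Constants in g.
COUNTS_BAND_HZ = (0.29, 1.63)
COUNTS_DEADBAND_G = 0.068
COUNTS_SATURATION_G = 2.13
COUNTS_RESOLUTION_G = 0.0164


def activity_counts(
    recording: Recording,
    epoch_s: float = 1.0,
    band_hz: tuple[float, float] = COUNTS_BAND_HZ,
    deadband_g: float = COUNTS_DEADBAND_G,
    saturation_g: float = COUNTS_SATURATION_G,
    resolution_g: float = COUNTS_RESOLUTION_G,
) -> np.ndarray:
    """Per-epoch activity counts (vector magnitude across axes).

    Pipeline per axis: band-pass -> rectify -> dead-band -> clip at
    saturation -> quantize by the count resolution -> sum per epoch.  The
    per-epoch vector magnitude across the three axes is returned;
    non-negative by construction.
    """
    if epoch_s < 1.0 / recording.fs:
        raise ValueError("epoch_s must be at least one sample period")
    filtered = apply_filter(
        recording.acc, FilterSpec("bandpass", band_hz, order=4), recording.fs
    )
    rect = np.abs(filtered)
    rect[rect < deadband_g] = 0.0
    rect = np.minimum(rect, saturation_g)
    quantized = np.floor(rect / resolution_g)

    n_epoch_samples = int(round(epoch_s * recording.fs))
    n_epochs = int(np.ceil(recording.n_samples / n_epoch_samples))
    pad = n_epochs * n_epoch_samples - recording.n_samples
    if pad:
        quantized = np.vstack([quantized, np.zeros((pad, 3))])
    per_axis = quantized.reshape(n_epochs, n_epoch_samples, 3).sum(axis=1)
    return np.linalg.norm(per_axis, axis=1)


def resample_to(recording: Recording, target_fs: float) -> Recording:
    """Polyphase rational resampling to ``target_fs``."""
    if np.isclose(recording.fs, target_fs):
        return recording
    from fractions import Fraction

    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    acc = signal.resample_poly(recording.acc, frac.numerator, frac.denominator, axis=0)
    return Recording(
        fs=target_fs,
        acc=acc,
        subject_id=recording.subject_id,
        group=recording.group,
        meta=dict(recording.meta),
    )
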