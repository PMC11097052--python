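"""Synthetic wrist-accelerometer recordings with exact gait ground truth.

The generator produces long recordings assembled from scheduled segments of
three kinds:

``gait``
    A slowly rotating gravity unit vector plus a periodic arm-swing
    oscillation.  The component parallel to gravity carries the dominant
    step-frequency harmonic plus a stride-frequency subharmonic; a
    perpendicular component oscillates at stride frequency (arm swing
    proper).  White noise is added on every axis.
``rest``
    Gravity plus white noise only.
``arm_activity``
    Gravity plus band-limited (0.3-3 Hz) aperiodic bursts with amplitude
    comparable to gait — a stress test for false positives.

Ground truth (gait intervals and per-step events) is exact by construction
and returned alongside the signal, standing in for a multisensor reference
system.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core import GaitSequence, GSList, Recording, StepEvents

__all__ = [
    "Segment",
    "SimConfig",
    "AnnotatedRecording",
    "generate_recording",
    "make_validation_corpus",
    "GROUP_PROFILES",
]

#: Factor applied to swing amplitude when a bilateral walking aid
#: (rollator, walker, two crutches) suppresses arm swing.
BILATERAL_SUPPRESSION = 0.15


@dataclass(frozen=True)
class Segment:
    """One scheduled segment of a synthetic recording."""

    kind: str  # "gait" | "rest" | "arm_activity"
    duration_s: float
    step_freq_hz: float = 1.8  # steps per second (gait only)
    swing_amp_g: float = 0.3  # peak arm-swing amplitude (gait only)
    noise_sd_g: float = 0.01
    activity_amp_g: float = 0.25  # burst amplitude (arm_activity only)

    def __post_init__(self):
        if self.kind not in ("gait", "rest", "arm_activity"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.duration_s > 0:
            raise ValueError("segment duration must be > 0")
        if self.swing_amp_g < 0 or self.noise_sd_g < 0:
            raise ValueError("amplitudes must be >= 0")
        if not self.step_freq_hz > 0:
            raise ValueError("step_freq_hz must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic recording."""

    schedule: tuple[Segment, ...]
    fs: float = 100.0
    drift_rate: float = 0.01  # gravity-axis rotation rate, rad/s
    walking_aid_mode: str = "none"  # "none" | "bilateral"
    aid_suppression: float = BILATERAL_SUPPRESSION
    seed: int = 0
    subject_id: str = "sim"
    group: str = ""

    def __post_init__(self):
        if not self.schedule:
            raise ValueError("schedule must contain at least one segment")
        if self.walking_aid_mode not in ("none", "bilateral"):
            raise ValueError(f"unknown walking_aid_mode {self.walking_aid_mode!r}")
        object.__setattr__(self, "schedule", tuple(self.schedule))


@dataclass(frozen=True)
class AnnotatedRecording:
    """A synthetic recording with exact reference annotations."""

    recording: Recording
    truth: GSList
    step_truth: StepEvents


def _orthobasis(grav: np.ndarray) -> np.ndarray:
    """Unit vectors orthogonal to per-sample gravity directions (n, 3)."""
    ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(grav, ref)
    norms = np.linalg.norm(perp, axis=1, keepdims=True)
    # gravity never aligns with y in this generator (rotation in x-z plane)
    return perp / norms


def _band_noise(rng, n: int, fs: float, lo: float = 0.3, hi: float = 3.0) -> np.ndarray:
    raw = rng.standard_normal(n)
    if n < 30:
        return raw
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, raw)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def generate_recording(config: SimConfig) -> AnnotatedRecording:
    """Synthesize one recording from a :class:`SimConfig`, deterministically.

    Draw order: for each segment in schedule order, the per-axis noise block
    is drawn first, then any segment-specific random content (arm-activity
    bursts).  Identical seeds therefore reproduce the signal bit-for-bit.
    """
    fs = config.fs
    starts_s = np.concatenate(
        [[0.0], np.cumsum([seg.duration_s for seg in config.schedule])]
    )
    n_per_seg = [
        int(round(starts_s[i + 1] * fs)) - int(round(starts_s[i] * fs))
        for i in range(len(config.schedule))
    ]
    n_total = sum(n_per_seg)
    if n_total < 1:
        raise ValueError("schedule too short for the sampling rate")

    t = np.arange(n_total) / fs
    theta = config.drift_rate * t
    grav = np.column_stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)])
    perp = _orthobasis(grav)

    rng = np.random.default_rng(config.seed)
    acc = grav.copy()
    suppression = (
        config.aid_suppression if config.walking_aid_mode == "bilateral" else 1.0
    )

    truth: list[GaitSequence] = []
    step_times: list[float] = []
    offset = 0
    for seg, n, seg_start in zip(config.schedule, n_per_seg, starts_s[:-1]):
        idx = slice(offset, offset + n)
        acc[idx] += rng.normal(0.0, seg.noise_sd_g, size=(n, 3))
        if seg.kind == "gait":
            amp = seg.swing_amp_g * suppression
            tau = t[idx] - t[idx.start]
            f_step = seg.step_freq_hz
            f_str = f_step / 2.0
            par = amp * (
                np.sin(2 * np.pi * f_step * tau) + 0.4 * np.sin(2 * np.pi * f_str * tau)
            )
            prp = 0.6 * amp * np.sin(2 * np.pi * f_str * tau)
            acc[idx] += par[:, None] * grav[idx] + prp[:, None] * perp[idx]
            seg_end = seg_start + seg.duration_s
            if truth and abs(truth[-1].end_s - seg_start) < 1e-9:
                truth[-1] = GaitSequence(truth[-1].start_s, seg_end)
            else:
                truth.append(GaitSequence(seg_start, seg_end))
            k = np.arange(int(np.ceil(seg.duration_s * f_step)))
            times = seg_start + k / f_step
            step_times.extend(times[times < seg_end - 1e-9].tolist())
        elif seg.kind == "arm_activity":
            envelope = np.abs(_band_noise(rng, n, fs, 0.05, 0.3)) if n >= 30 else np.ones(n)
            for ax in range(3):
                burst = _band_noise(rng, n, fs) * envelope
                acc[idx.start : idx.start + n, ax] += seg.activity_amp_g * burst
        offset += n

    rec = Recording(
        fs=fs,
        acc=acc,
        subject_id=config.subject_id,
        group=config.group,
        meta={
            "walking_aid": "bilateral" if config.walking_aid_mode == "bilateral" else "none",
            "seed": config.seed,
        },
    )
    return AnnotatedRecording(
        recording=rec,
        truth=GSList(tuple(truth), source="reference"),
        step_truth=StepEvents(tuple(step_times)),
    )


#: Per-cohort generator profiles.  Ranges are (low, high) for uniform draws.
#: Impaired cohorts walk with lower arm swing, slower cadence, and shorter,
#: in some cases more fragmented, bouts.
GROUP_PROFILES: dict[str, dict] = {
    "HA": dict(n_bouts=(6, 9), bout_s=(40, 90), swing=(0.30, 0.50), f_step=(1.8, 2.2)),
    "CHF": dict(n_bouts=(4, 6), bout_s=(30, 60), swing=(0.25, 0.40), f_step=(1.6, 2.0)),
    "COPD": dict(n_bouts=(4, 7), bout_s=(25, 60), swing=(0.25, 0.40), f_step=(1.6, 2.0)),
    "MS": dict(n_bouts=(3, 6), bout_s=(20, 50), swing=(0.20, 0.35), f_step=(1.5, 1.9)),
    "PD": dict(n_bouts=(3, 6), bout_s=(20, 50), swing=(0.20, 0.35), f_step=(1.5, 1.9)),
    "PFF": dict(n_bouts=(2, 5), bout_s=(15, 35), swing=(0.15, 0.28), f_step=(1.4, 1.7)),
}
_DEFAULT_PROFILE = GROUP_PROFILES["CHF"]


def _subject_schedule(rng, profile: dict, duration_s: float) -> tuple[Segment, ...]:
    """Random schedule: gait bouts separated by rest / arm activity filler.

    Bout counts and durations are capped so total gait stays below half the
    requested duration and every inter-bout gap is at least 5 s.
    """
    n_bouts = int(rng.integers(profile["n_bouts"][0], profile["n_bouts"][1] + 1))
    n_bouts = min(n_bouts, max(1, int(duration_s // 30)))
    bouts = [
        Segment(
            "gait",
            duration_s=float(rng.uniform(*profile["bout_s"])),
            step_freq_hz=float(rng.uniform(*profile["f_step"])),
            swing_amp_g=float(rng.uniform(*profile["swing"])),
        )
        for _ in range(n_bouts)
    ]
    gait_total = sum(b.duration_s for b in bouts)
    if gait_total > 0.5 * duration_s:
        scale = 0.5 * duration_s / gait_total
        bouts = [replace(b, duration_s=b.duration_s * scale) for b in bouts]
        gait_total = sum(b.duration_s for b in bouts)
    filler_total = max(duration_s - gait_total, 10.0 * (n_bouts + 1))
    # split filler into n_bouts+1 gaps, each at least 5 s so bouts never merge
    w = rng.dirichlet(np.ones(n_bouts + 1)) * (filler_total - 5.0 * (n_bouts + 1))
    schedule: list[Segment] = []
    for i, bout in enumerate(bouts):
        gap = 5.0 + float(w[i])
        kind = "arm_activity" if rng.random() < 0.35 and gap > 15 else "rest"
        schedule.append(Segment(kind, duration_s=gap))
        schedule.append(bout)
    schedule.append(Segment("rest", duration_s=5.0 + float(w[-1])))
    return tuple(schedule)


def make_validation_corpus(
    n_subjects: int | None = None,
    per_group: dict[str, int] | None = None,
    seed: int = 0,
    duration_s: float = 600.0,
    walking_aid_mode: str = "none",
) -> list[AnnotatedRecording]:
    """Generate a multi-cohort corpus of annotated recordings.

    Either ``per_group`` (group label -> count) or ``n_subjects`` (spread
    evenly over the six built-in cohorts) must be given.  Deterministic for
    a fixed seed: subject schedules are drawn from a single master stream
    in group-then-subject order, and each subject's signal uses a child
    seed drawn from that stream.
    """
    if per_group is None:
        if n_subjects is None:
            raise ValueError("provide n_subjects or per_group")
        groups = list(GROUP_PROFILES)
        per_group = {g: 0 for g in groups}
        for i in range(n_subjects):
            per_group[groups[i % len(groups)]] += 1
        per_group = {g: c for g, c in per_group.items() if c > 0}
    if any(c < 1 for c in per_group.values()):
        raise ValueError("per-group counts must be >= 1")

    master = np.random.default_rng(seed)
    corpus: list[AnnotatedRecording] = []
    for group in per_group:
        profile = GROUP_PROFILES.get(group, _DEFAULT_PROFILE)
        for i in range(per_group[group]):
            schedule = _subject_schedule(master, profile, duration_s)
            child_seed = int(master.integers(0, 2**31 - 1))
            cfg = SimConfig(
                schedule=schedule,
                seed=child_seed,
                subject_id=f"{group}{i + 1:03d}",
                group=group,
                walking_aid_mode=walking_aid_mode,
            )
            corpus.append(generate_recording(cfg))
    return corpus


def with_walking_aid(config: SimConfig) -> SimConfig:
    """Bilateral-aid twin of a config: same schedule, seed and drift."""
    return replace(config, walking_aid_mode="bilateral")
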