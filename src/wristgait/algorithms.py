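"""Gait-sequence detectors for wrist-worn triaxial accelerometry.

Seven detectors share a uniform contract: ``Recording -> GSList``.  Each is
a concrete, testable pipeline built around the orientation-independent
acceleration norm (the wrist-specific substitution for axis-dependent
signals), with interior constants exposed as parameters.

Thresholds are in g throughout.  Parameter banks ("default" and
"optimized") ship in ``data/params.yaml``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import yaml
from scipy import signal

from .core import (
    GaitSequence,
    GSList,
    Recording,
    StepEvents,
    StrideIntervals,
    assemble_gs_from_events,
    merge_overlapping,
)
from .preprocessing import (
    FilterSpec,
    accel_norm,
    activity_counts,
    apply_filter,
    estimate_vertical,
    moving_stat,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParaschivParams",
    "Paraschiv2020Params",
    "IluzParams",
    "GuParams",
    "KarasParams",
    "HickeyParams",
    "KheirkhahanParams",
    "detect_paraschiv2019",
    "detect_paraschiv2020",
    "detect_iluz",
    "detect_gu",
    "detect_karas",
    "detect_hickey",
    "detect_kheirkhahan",
    "run_algorithm",
    "load_param_bank",
    "REGISTRY",
]

#: Minimum separation of step peaks, seconds.
MIN_PEAK_DISTANCE_S = 0.25
#: Plausible inter-step interval band for periodicity checks, seconds.
PERIODICITY_BAND_S = (0.25, 2.0)
#: Step of the candidate stride-duration grid, seconds.
DURATION_GRID_STEP_S = 0.05
#: Internal rate at which block-maxima step candidates are extracted.
VERISENSE_RATE_HZ = 15.0


# ---------------------------------------------------------------------------
# parameter types


@dataclass(frozen=True)
class ParaschivParams:
    """Step-peak detection on the smoothed, gravity-subtracted norm."""

    th: float = 0.1
    max_step_gap_s: float = 3.0
    min_steps: int = 3
    smooth_cutoff_hz: float = 3.5

    def __post_init__(self):
        if not self.th > 0:
            raise ValueError("th must be > 0")


@dataclass(frozen=True)
class Paraschiv2020Params:
    """Adaptive-threshold variant with iterative smoothing/enhancement."""

    n_smooth_iters: int = 2
    adapt_quantile: float = 0.1
    adapt_floor_g: float = 0.12
    max_step_gap_s: float = 3.0
    min_steps: int = 3
    smooth_cutoff_hz: float = 3.5
    smooth_window_s: float = 0.05

    def __post_init__(self):
        if not 0 < self.adapt_quantile < 1:
            raise ValueError("adapt_quantile must lie in (0, 1)")


@dataclass(frozen=True)
class IluzParams:
    """Sine-template convolution with a variance gate."""

    activity_thres: float = 0.01  # g^2
    min_bout_length: float = 5.0  # s
    template_len: float = 0.5  # s
    cm_norm_thres: float = 0.4
    variance_window_s: float = 1.0
    max_gap_s: float = 3.0

    def __post_init__(self):
        for name in ("activity_thres", "min_bout_length", "template_len", "cm_norm_thres"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class GuParams:
    """Block-maxima step candidates filtered by magnitude, similarity, continuity."""

    verisense_k: int = 3  # peak-search block, samples at the internal rate
    sim_thres: float = -0.5  # negated absolute amplitude difference, g
    cont_thres: int = 4  # minimum consecutive plausible steps
    mag_thres: float = 1.2  # g, on the raw norm
    max_step_gap_s: float = 3.0

    def __post_init__(self):
        if self.verisense_k < 1 or self.cont_thres < 1:
            raise ValueError("verisense_k and cont_thres must be >= 1")
        if not self.mag_thres > 0:
            raise ValueError("mag_thres must be > 0")


@dataclass(frozen=True)
class KarasParams:
    """Scaled-template stride matching with run-consistency filters."""

    sim_MIN: float = 0.85
    dur_MIN: float = 0.8  # s
    dur_MAX: float = 1.4  # s
    ptp_r_MIN: float = 0.2  # g
    ptp_r_MAX: float = 2.0  # g
    mean_abs_diff_med_p_MAX: float = 0.5
    mean_abs_diff_med_t_MAX: float = 0.2
    mean_abs_diff_dur_MAX: float = 0.2
    templates: tuple = ()  # unit-scale stride patterns; empty -> built-in bank
    max_gap_s: float = 3.0

    def __post_init__(self):
        if not self.dur_MIN < self.dur_MAX:
            raise ValueError("dur_MIN must be < dur_MAX")
        if not self.ptp_r_MIN < self.ptp_r_MAX:
            raise ValueError("ptp_r_MIN must be < ptp_r_MAX")
        if not -1 <= self.sim_MIN <= 1:
            raise ValueError("sim_MIN must lie in [-1, 1]")


@dataclass(frozen=True)
class HickeyParams:
    """Windowed still/upright gating on combined SD and vertical mean."""

    ThresholdStill: float = 0.2  # g
    ThresholdUpright: float = -0.5  # g, on (vertical - 1 g)
    window_s: float = 0.1
    sd_window_s: float = 1.0  # span of the moving SD (covers >= one stride)
    max_gap_s: float = 3.0

    def __post_init__(self):
        if not self.window_s > 0:
            raise ValueError("window_s must be > 0")


@dataclass(frozen=True)
class KheirkhahanParams:
    """Activity-count classification over sliding epoch windows."""

    walking_threshold: float = 0.75
    epoch_s: float = 1.0
    window_epochs: int = 10
    level_fraction: float = 0.5  # adaptive level = fraction * median nonzero count
    max_gap_s: float = 3.0

    def __post_init__(self):
        if not 0 < self.walking_threshold <= 1:
            raise ValueError("walking_threshold must lie in (0, 1]")


# ---------------------------------------------------------------------------
# helpers


def _merge_with_gap(intervals, max_gap_s: float, source: str) -> GSList:
    """Union intervals, then merge any pair separated by <= max_gap_s."""
    union = merge_overlapping(intervals)
    merged: list[list[float]] = []
    for gs in union:
        if merged and gs.start_s - merged[-1][1] <= max_gap_s:
            merged[-1][1] = gs.end_s
        else:
            merged.append([gs.start_s, gs.end_s])
    return GSList(tuple(GaitSequence(a, b) for a, b in merged), source=source)


def _detrended_norm(recording: Recording, cutoff_hz: float | None = None) -> np.ndarray:
    d = accel_norm(recording) - 1.0
    if cutoff_hz is not None and recording.n_samples > 24:
        d = apply_filter(d, FilterSpec("lowpass", cutoff_hz), recording.fs)
    return d


# ---------------------------------------------------------------------------
# detectors


def detect_paraschiv2019(recording: Recording, params: ParaschivParams) -> GSList:
    """Step peaks on the smoothed gravity-subtracted norm, assembled to GSs."""
    smoothed = _detrended_norm(recording, params.smooth_cutoff_hz)
    distance = max(int(round(MIN_PEAK_DISTANCE_S * recording.fs)), 1)
    peaks, _ = signal.find_peaks(smoothed, height=params.th, distance=distance)
    steps = StepEvents(tuple(peaks / recording.fs))
    return assemble_gs_from_events(
        steps,
        max_gap_s=params.max_step_gap_s,
        min_events=params.min_steps,
        source="paraschiv2019",
    )


def _enhance(series: np.ndarray, fs: float, n_iters: int, window_s: float) -> np.ndarray:
    """Iterative smoothing + sign-preserving square enhancement.

    Each round: centered moving average, then ``sign(x) * x**2``.  The final
    signal is mapped back to the g scale through the inverse power, so
    thresholds keep their physical meaning while repeated squaring (between
    smoothing passes) suppresses the noise floor relative to step peaks.
    """
    x = np.asarray(series, dtype=float)
    for _ in range(n_iters):
        x = moving_stat(x, window_s, "mean", fs)
        x = np.sign(x) * x**2
    if n_iters:
        x = np.sign(x) * np.abs(x) ** (1.0 / 2**n_iters)
    return x


def detect_paraschiv2020(recording: Recording, params: Paraschiv2020Params) -> GSList:
    """Adaptive-threshold step detection; no manual threshold required.

    A permissive pass at the amplitude floor collects candidate peak
    heights; the working threshold is the ``adapt_quantile`` quantile of
    those heights, never below ``adapt_floor_g``.
    """
    enhanced = _enhance(
        _detrended_norm(recording, params.smooth_cutoff_hz),
        recording.fs,
        params.n_smooth_iters,
        params.smooth_window_s,
    )
    distance = max(int(round(MIN_PEAK_DISTANCE_S * recording.fs)), 1)
    candidates, props = signal.find_peaks(
        enhanced, height=params.adapt_floor_g, distance=distance
    )
    if candidates.size == 0:
        return GSList((), source="paraschiv2020")
    th = max(
        params.adapt_floor_g,
        float(np.quantile(props["peak_heights"], params.adapt_quantile)),
    )
    peaks, _ = signal.find_peaks(enhanced, height=th, distance=distance)
    steps = StepEvents(tuple(peaks / recording.fs))
    return assemble_gs_from_events(
        steps,
        max_gap_s=params.max_step_gap_s,
        min_events=params.min_steps,
        source="paraschiv2020",
    )


def detect_iluz(recording: Recording, params: IluzParams) -> GSList:
    """Sine-template convolution maxima gated by a moving-variance test."""
    d = _detrended_norm(recording)
    fs = recording.fs
    length = max(int(round(params.template_len * fs)), 2)
    template = np.sin(2 * np.pi * np.arange(length) / length)
    conv = signal.fftconvolve(d, template[::-1], mode="same")

    var = moving_stat(d, params.variance_window_s, "sd", fs) ** 2
    active = var > params.activity_thres

    distance = max(int(round(MIN_PEAK_DISTANCE_S * fs)), 1)
    maxima, _ = signal.find_peaks(
        np.abs(conv), height=params.cm_norm_thres, distance=distance
    )
    maxima = maxima[active[maxima]]
    if maxima.size == 0:
        return GSList((), source="iluz")

    gs = assemble_gs_from_events(
        StepEvents(tuple(maxima / fs)),
        max_gap_s=params.max_gap_s,
        min_events=2,
        source="iluz",
    )
    kept = tuple(g for g in gs if g.duration_s >= params.min_bout_length)
    return GSList(kept, source="iluz")


def detect_gu(recording: Recording, params: GuParams) -> GSList:
    """Magnitude / similarity / continuity filtering of norm peaks.

    The norm is decimated to an internal candidate rate (15 Hz) and peak
    candidates are block maxima separated by at least ``verisense_k``
    samples at that rate.  A candidate is a step if its magnitude exceeds
    ``mag_thres``, neighboring peak amplitudes differ by at most
    ``-sim_thres`` g, and it sits in a run of at least ``cont_thres``
    candidates with inter-peak intervals inside the plausible band.
    """
    norm = accel_norm(recording)
    fs = recording.fs
    if fs > VERISENSE_RATE_HZ:
        decim = int(round(fs / VERISENSE_RATE_HZ))
        internal = signal.resample_poly(norm, 1, decim)
        internal_fs = fs / decim
    else:
        internal, internal_fs = norm, fs
    peaks, props = signal.find_peaks(internal, distance=max(params.verisense_k, 1))
    if peaks.size == 0:
        return GSList((), source="gu")
    amps = internal[peaks]
    times = peaks / internal_fs

    ok_mag = amps > params.mag_thres
    tol = -params.sim_thres
    ok_sim = np.ones_like(ok_mag)
    if peaks.size > 1:
        diff_next = np.abs(np.diff(amps))
        # a peak is similar if it matches either neighbor within tolerance
        ok_sim[:-1] = diff_next <= tol
        ok_sim[1:] |= diff_next <= tol
    accepted = ok_mag & ok_sim

    acc_times = times[accepted]
    if acc_times.size == 0:
        return GSList((), source="gu")
    lo, hi = PERIODICITY_BAND_S
    gaps = np.diff(acc_times)
    plausible = (gaps >= lo) & (gaps <= hi)
    # runs of candidates chained by plausible intervals
    steps: list[float] = []
    run = [acc_times[0]]
    for i, good in enumerate(plausible):
        if good:
            run.append(acc_times[i + 1])
        else:
            if len(run) >= params.cont_thres:
                steps.extend(run)
            run = [acc_times[i + 1]]
    if len(run) >= params.cont_thres:
        steps.extend(run)
    return assemble_gs_from_events(
        StepEvents(tuple(steps)),
        max_gap_s=params.max_step_gap_s,
        min_events=max(params.cont_thres, 2),
        source="gu",
    )


def _default_templates() -> tuple[np.ndarray, ...]:
    """Built-in stride patterns: one-period sine and a harmonic mixture."""
    u = np.linspace(0.0, 1.0, 200, endpoint=False)
    t1 = np.sin(2 * np.pi * u)
    t2 = 0.4 * np.sin(2 * np.pi * u) + np.sin(4 * np.pi * u)
    return (t1, t2)


def _normalized(template: np.ndarray, length: int) -> np.ndarray:
    """Resample a template to `length` samples, zero-mean, unit norm."""
    src = np.asarray(template, dtype=float)
    pos = np.linspace(0, src.size - 1, length)
    resampled = np.interp(pos, np.arange(src.size), src)
    resampled = resampled - resampled.mean()
    nrm = np.linalg.norm(resampled)
    return resampled / nrm if nrm > 0 else resampled


def detect_karas(recording: Recording, params: KarasParams) -> GSList:
    """Template-matching stride detection with greedy non-overlap selection.

    For every duration on a grid over ``[dur_MIN, dur_MAX]`` the normalized
    correlation between each rescaled template and the smoothed norm is
    computed by sliding inner products.  Local correlation maxima above
    ``sim_MIN`` whose window peak-to-peak lies within the admissible range
    become stride candidates; candidates are accepted greedily (highest
    similarity first, earlier onset breaks ties) subject to non-overlap.
    Runs of consecutive accepted strides with inconsistent peak, trough or
    duration statistics are rejected wholesale.
    """
    templates = tuple(params.templates) or _default_templates()
    if not templates:
        raise ValueError("at least one template is required")
    fs = recording.fs
    d = _detrended_norm(recording, cutoff_hz=5.0 if fs > 12 else None)
    n = d.size

    cs = np.concatenate([[0.0], np.cumsum(d)])
    cs2 = np.concatenate([[0.0], np.cumsum(d * d)])

    durations = np.arange(params.dur_MIN, params.dur_MAX + 1e-9, DURATION_GRID_STEP_S)
    cand_on, cand_len, cand_sim = [], [], []
    for dur in durations:
        length = int(round(dur * fs))
        if length < 4 or length > n:
            continue
        onsets = np.arange(n - length + 1)
        win_sum = cs[length:] - cs[:-length]
        win_sq = cs2[length:] - cs2[:-length]
        denom = np.sqrt(np.maximum(win_sq - win_sum**2 / length, 1e-300))
        for template in templates:
            tpl = _normalized(template, length)
            num = signal.fftconvolve(d, tpl[::-1], mode="valid")
            rho = num / denom
            peaks, props = signal.find_peaks(
                rho, height=params.sim_MIN, distance=max(length // 2, 1)
            )
            if peaks.size == 0:
                continue
            cand_on.append(onsets[peaks])
            cand_len.append(np.full(peaks.size, length))
            cand_sim.append(props["peak_heights"])
    if not cand_on:
        return GSList((), source="karas")

    onset = np.concatenate(cand_on)
    length = np.concatenate(cand_len)
    sim = np.concatenate(cand_sim)

    # cheap peak-to-peak filter before the greedy pass
    ptp = np.array([np.ptp(d[i : i + l]) for i, l in zip(onset, length)])
    keep = (ptp >= params.ptp_r_MIN) & (ptp <= params.ptp_r_MAX)
    onset, length, sim = onset[keep], length[keep], sim[keep]
    if onset.size == 0:
        return GSList((), source="karas")

    order = np.lexsort((onset, -sim))
    occupied = np.zeros(n, dtype=bool)
    strides: list[tuple[int, int]] = []
    for j in order:
        i, l = int(onset[j]), int(length[j])
        if not occupied[i : i + l].any():
            occupied[i : i + l] = True
            strides.append((i, i + l))
    strides.sort()

    # per-stride features for run-consistency filtering
    feats = []
    for a, b in strides:
        seg = d[a:b]
        pk, _ = signal.find_peaks(seg)
        tr, _ = signal.find_peaks(-seg)
        med_p = float(np.median(seg[pk])) if pk.size else float(seg.max())
        med_t = float(np.median(seg[tr])) if tr.size else float(seg.min())
        feats.append((med_p, med_t, (b - a) / fs))
    feats = np.array(feats)

    survivors: list[tuple[float, float]] = []
    run: list[int] = []

    def flush(run_idx: list[int]):
        if len(run_idx) >= 2:
            f = feats[run_idx]
            if (
                np.mean(np.abs(np.diff(f[:, 0]))) > params.mean_abs_diff_med_p_MAX
                or np.mean(np.abs(np.diff(f[:, 1]))) > params.mean_abs_diff_med_t_MAX
                or np.mean(np.abs(np.diff(f[:, 2]))) > params.mean_abs_diff_dur_MAX
            ):
                return
        survivors.extend((strides[i][0] / fs, strides[i][1] / fs) for i in run_idx)

    for idx, (a, b) in enumerate(strides):
        if run and a - strides[run[-1]][1] > params.max_gap_s * fs:
            flush(run)
            run = []
        run.append(idx)
    flush(run)

    return assemble_gs_from_events(
        StrideIntervals(tuple(survivors)),
        max_gap_s=params.max_gap_s,
        min_events=2,
        source="karas",
    )


def detect_hickey(recording: Recording, params: HickeyParams) -> GSList:
    """Combined-SD and vertical-mean window gating.

    Per non-overlapping window of ``window_s``: "moving" if the combined SD
    (root of the summed per-axis variances, a rotation-invariant quantity,
    taken over a ``sd_window_s`` moving span so at least one gait cycle is
    covered) exceeds ``ThresholdStill``; "upright" if the window-mean
    vertical acceleration minus 1 g exceeds ``ThresholdUpright``.  Gait
    windows are those both moving and upright, merged under the gap rule.
    """
    fs = recording.fs
    w = max(int(round(params.window_s * fs)), 1)
    n_win = recording.n_samples // w
    if n_win == 0:
        return GSList((), source="hickey")
    var_sum = sum(
        moving_stat(recording.acc[:, ax], params.sd_window_s, "sd", fs) ** 2
        for ax in range(3)
    )
    comb_sd = np.sqrt(var_sum[: n_win * w]).reshape(n_win, w).mean(axis=1)
    vertical = estimate_vertical(recording)[: n_win * w].reshape(n_win, w).mean(axis=1)

    gait = (comb_sd > params.ThresholdStill) & (vertical - 1.0 > params.ThresholdUpright)
    idx = np.flatnonzero(gait)
    if idx.size == 0:
        return GSList((), source="hickey")
    intervals = [(i * w / fs, (i + 1) * w / fs) for i in idx]
    return _merge_with_gap(intervals, params.max_gap_s, source="hickey")


def detect_kheirkhahan(recording: Recording, params: KheirkhahanParams) -> GSList:
    """Activity-count walking classification over sliding epoch windows.

    The adaptive level is a fraction of the median nonzero epoch count of
    the recording (stand-in for the unspecified original rule).  An epoch
    is walking when the fraction of epochs in its centered window with
    counts above the level exceeds ``walking_threshold``.
    """
    counts = activity_counts(recording, epoch_s=params.epoch_s)
    nonzero = counts[counts > 0]
    if nonzero.size == 0:
        return GSList((), source="kheirkhahan")
    level = params.level_fraction * float(np.median(nonzero))
    active = (counts > level).astype(float)
    frac = moving_stat(active, params.window_epochs * 1.0, "mean", fs=1.0)
    walking = np.flatnonzero(frac > params.walking_threshold)
    if walking.size == 0:
        return GSList((), source="kheirkhahan")
    e = params.epoch_s
    duration = recording.duration_s
    intervals = [(i * e, min((i + 1) * e, duration)) for i in walking]
    intervals = [(a, b) for a, b in intervals if b > a]
    return _merge_with_gap(intervals, params.max_gap_s, source="kheirkhahan")


# ---------------------------------------------------------------------------
# registry and parameter banks

REGISTRY: dict[str, tuple] = {
    "paraschiv2019": (detect_paraschiv2019, ParaschivParams),
    "paraschiv2020": (detect_paraschiv2020, Paraschiv2020Params),
    "iluz": (detect_iluz, IluzParams),
    "gu": (detect_gu, GuParams),
    "karas": (detect_karas, KarasParams),
    "hickey": (detect_hickey, HickeyParams),
    "kheirkhahan": (detect_kheirkhahan, KheirkhahanParams),
}


def load_param_bank() -> dict:
    """Load the shipped default/optimized parameter bank."""
    text = resources.files("wristgait").joinpath("data/params.yaml").read_text()
    return yaml.safe_load(text)


def make_params(name: str, bank: str = "optimized", **overrides):
    """Build a parameter object for a registered detector."""
    if name not in REGISTRY:
        raise KeyError(
            f"unknown algorithm {name!r}; registered: {sorted(REGISTRY)}"
        )
    _, params_cls = REGISTRY[name]
    values: dict = {}
    if bank is not None:
        bank_values = load_param_bank()[name][bank]
        valid = {f.name for f in fields(params_cls)}
        values.update({k: v for k, v in bank_values.items() if k in valid})
    values.update(overrides)
    return params_cls(**values)


def run_algorithm(
    name: str,
    recording: Recording,
    bank: str = "optimized",
    params=None,
    **overrides,
) -> GSList:
    """Dispatch a registered detector with bank defaults or explicit params."""
    if name not in REGISTRY:
        raise KeyError(
            f"unknown algorithm {name!r}; registered: {sorted(REGISTRY)}"
        )
    detector, params_cls = REGISTRY[name]
    if params is None:
        params = make_params(name, bank=bank, **overrides)
    elif overrides:
        params = replace(params, **overrides)
    logger.info("running %s with %s", name, params)
    return detector(recording, params)
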