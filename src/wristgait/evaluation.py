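"""Per-recording validation: window rasterization, confusion counts,
classification metrics, and gait-sequence count/duration errors.

Recordings are segmented into fixed-grid windows (default 0.1 s); a window
is labeled gait iff its midpoint falls inside any gait sequence.  Undefined
ratios (zero denominators) are returned as NaN and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GSList

__all__ = [
    "WindowLabels",
    "ConfusionCounts",
    "MetricPanel",
    "rasterize",
    "confusion",
    "classification_metrics",
    "gs_errors",
    "evaluate_recording",
]


@dataclass(frozen=True)
class WindowLabels:
    """Boolean gait/non-gait labels on a fixed window grid."""

    labels: np.ndarray
    window_s: float = 0.1

    def __post_init__(self):
        if not self.window_s > 0:
            raise ValueError("window_s must be > 0")
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=bool))

    def __len__(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricPanel:
    """The per-recording metric set.

    Fractions lie in [0, 1] (NaN when undefined); errors are percentages.
    Carries the raw counts/durations needed for group-level ICC.
    """

    sensitivity: float
    specificity: float
    ppv: float
    accuracy: float
    gs_count_rel_err: float
    gs_count_rel_abs_err: float
    gs_dur_rel_err: float
    gs_dur_rel_abs_err: float
    gs_dur_pred_s: float = float("nan")
    gs_dur_ref_s: float = float("nan")
    gs_count_pred: int = 0
    gs_count_ref: int = 0
    subject_id: str = ""
    group: str = ""

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "gs_count_rel_err": self.gs_count_rel_err,
            "gs_count_rel_abs_err": self.gs_count_rel_abs_err,
            "gs_dur_rel_err": self.gs_dur_rel_err,
            "gs_dur_rel_abs_err": self.gs_dur_rel_abs_err,
            "gs_dur_pred_s": self.gs_dur_pred_s,
            "gs_dur_ref_s": self.gs_dur_ref_s,
            "gs_count_pred": self.gs_count_pred,
            "gs_count_ref": self.gs_count_ref,
        }


def rasterize(gs: GSList, duration_s: float, window_s: float = 0.1) -> WindowLabels:
    """Label fixed-grid windows by the midpoint-in-sequence rule."""
    arr = gs.as_array()
    if arr.size and arr[:, 1].max() > duration_s + 1e-9:
        raise ValueError("gait sequence extends beyond the recording duration")
    n = int(np.ceil(duration_s / window_s - 1e-9))
    mid = (np.arange(n) + 0.5) * window_s
    labels = np.zeros(n, dtype=bool)
    for start, end in arr:
        labels |= (mid >= start) & (mid < end)
    return WindowLabels(labels, window_s=window_s)


def confusion(pred: WindowLabels, ref: WindowLabels) -> ConfusionCounts:
    """Element-wise confusion counts for equally gridded label vectors."""
    if len(pred) != len(ref) or not np.isclose(pred.window_s, ref.window_s):
        raise ValueError(
            f"label grids differ: {len(pred)}@{pred.window_s}s vs "
            f"{len(ref)}@{ref.window_s}s"
        )
    p, r = pred.labels, ref.labels
    return ConfusionCounts(
        tp=int(np.sum(p & r)),
        fp=int(np.sum(p & ~r)),
        tn=int(np.sum(~p & ~r)),
        fn=int(np.sum(~p & r)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, ppv, accuracy); NaN where undefined."""
    return (
        _ratio(c.tp, c.tp + c.fn),
        _ratio(c.tn, c.tn + c.fp),
        _ratio(c.tp, c.tp + c.fp),
        _ratio(c.tp + c.tn, c.total),
    )


def gs_errors(pred: GSList, ref: GSList) -> tuple[float, float, float, float]:
    """Relative (and absolute) count and total-duration errors, percent.

    Undefined (NaN) when the reference is empty.
    """
    n_ref, n_pred = len(ref), len(pred)
    t_ref, t_pred = ref.total_duration_s, pred.total_duration_s
    count = 100.0 * (n_pred - n_ref) / n_ref if n_ref else float("nan")
    dur = 100.0 * (t_pred - t_ref) / t_ref if t_ref > 0 else float("nan")
    return count, abs(count), dur, abs(dur)


def evaluate_recording(
    pred: GSList,
    ref: GSList,
    duration_s: float,
    window_s: float = 0.1,
    subject_id: str = "",
    group: str = "",
) -> MetricPanel:
    """Full per-recording panel: rasterize -> confusion -> metrics + errors."""
    c = confusion(
        rasterize(pred, duration_s, window_s), rasterize(ref, duration_s, window_s)
    )
    sens, spec, ppv, acc = classification_metrics(c)
    cnt, cnt_abs, dur, dur_abs = gs_errors(pred, ref)
    return MetricPanel(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        accuracy=acc,
        gs_count_rel_err=cnt,
        gs_count_rel_abs_err=cnt_abs,
        gs_dur_rel_err=dur,
        gs_dur_rel_abs_err=dur_abs,
        gs_dur_pred_s=pred.total_duration_s,
        gs_dur_ref_s=ref.total_duration_s,
        gs_count_pred=len(pred),
        gs_count_ref=len(ref),
        subject_id=subject_id,
        group=group,
    )
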