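"""Group-level aggregation: ICC(2,1), composite performance index, paired
comparisons with Benjamini-Hochberg adjustment."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evaluation import MetricPanel

__all__ = [
    "ICCResult",
    "PerfWeights",
    "ComparisonResult",
    "GroupSummary",
    "icc_2_1",
    "interpret_icc",
    "performance_index",
    "paired_compare",
    "benjamini_hochberg",
    "summarize_group",
]

ICC_BANDS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"))

BENEFIT_METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "icc")
COST_METRICS = ("gs_dur_rel_abs_err", "gs_count_rel_abs_err")
ALL_INDEX_METRICS = BENEFIT_METRICS + COST_METRICS

#: Cap (percent) applied to cost metrics before [0, 1] normalization.
COST_CAP_PERCENT = 100.0


@dataclass(frozen=True)
class ICCResult:
    icc: float
    category: str
    n_subjects: int
    ms_rows: float
    ms_cols: float
    ms_err: float


@dataclass(frozen=True)
class PerfWeights:
    """Per-metric weights for the composite performance index.

    Benefits enter directly; costs are capped, normalized and inverted.
    Weights must be non-negative and sum to 1.
    """

    weights: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 / len(ALL_INDEX_METRICS) for m in ALL_INDEX_METRICS}
    )

    def __post_init__(self):
        w = dict(self.weights)
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be non-negative")
        total = sum(w.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")
        object.__setattr__(self, "weights", w)

    def without(self, metric: str) -> "PerfWeights":
        """Drop a metric and renormalize the remaining weights."""
        w = {k: v for k, v in self.weights.items() if k != metric}
        total = sum(w.values())
        return PerfWeights({k: v / total for k, v in w.items()})


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    mean_difference: float
    t_stat: float
    p_value: float
    p_adjusted: float = float("nan")
    degenerate: bool = False


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean_metrics: dict[str, float]
    icc: ICCResult | None
    performance_index: float


def icc_2_1(values: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``values`` is an (n_subjects, k) matrix; here k = 2 (algorithm vs
    reference total gait duration).  Mean squares come from the standard
    two-way ANOVA decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("values must be an n x k matrix with k >= 2")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects for ICC, got {n}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    icc = (ms_rows - ms_err) / denom if denom != 0 else float("nan")
    return ICCResult(
        icc=float(icc),
        category=interpret_icc(icc),
        n_subjects=n,
        ms_rows=float(ms_rows),
        ms_cols=float(ms_cols),
        ms_err=float(ms_err),
    )


def interpret_icc(icc: float) -> str:
    """Reliability bands; boundary values go to the higher category."""
    if not np.isfinite(icc):
        return "undefined"
    for bound, name in ICC_BANDS:
        if icc < bound:
            return name
    return "excellent"


def performance_index(group_metrics: dict[str, float], weights: PerfWeights | None = None) -> float:
    """Weighted [0, 1] combination of benefit and (inverted) cost metrics.

    Benefits contribute their value directly (clipped to [0, 1]); costs in
    percent are capped at :data:`COST_CAP_PERCENT`, scaled to [0, 1] and
    inverted so that 0% error contributes 1.
    """
    weights = weights or PerfWeights()
    index = 0.0
    for metric, w in weights.weights.items():
        if metric not in group_metrics:
            raise KeyError(f"performance index requires metric {metric!r}")
        value = group_metrics[metric]
        if not np.isfinite(value):
            raise ValueError(f"metric {metric!r} is not finite: {value}")
        if metric in COST_METRICS:
            contrib = 1.0 - min(abs(value), COST_CAP_PERCENT) / COST_CAP_PERCENT
        else:
            contrib = min(max(value, 0.0), 1.0)
        index += w * contrib
    return float(index)


def paired_compare(
    metric_a: np.ndarray, metric_b: np.ndarray, metric: str = ""
) -> ComparisonResult:
    """Two-sided paired t test on participant-level values (a - b).

    Zero variance of the differences is flagged degenerate: p = 1 when the
    constant difference is 0, else p = 0 (a certain difference).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("paired comparison needs equal-length 1-D arrays, n >= 3")
    d = a - b
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return ComparisonResult(
            metric=metric,
            mean_difference=mean,
            t_stat=float("inf") if mean != 0 else 0.0,
            p_value=0.0 if mean != 0 else 1.0,
            degenerate=True,
        )
    from scipy import stats as sps

    t = mean / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return ComparisonResult(metric=metric, mean_difference=mean, t_stat=float(t), p_value=float(p))


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up FDR adjustment: adj_(i) = min_{j >= i} (m p_(j) / j), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def _nanmean(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    return float(finite.mean()) if finite.size else float("nan")


def summarize_group(
    panels: list[MetricPanel],
    weights: PerfWeights | None = None,
) -> dict[str, GroupSummary]:
    """Per-group means, ICC of total gait duration, and performance index.

    Undefined (NaN) per-recording metrics are excluded from means.  Groups
    with fewer than 3 recordings get no ICC; the index is then computed
    with the ICC weight redistributed over the remaining metrics.
    """
    weights = weights or PerfWeights()
    by_group: dict[str, list[MetricPanel]] = {}
    for panel in panels:
        by_group.setdefault(panel.group, []).append(panel)

    summaries: dict[str, GroupSummary] = {}
    for group, members in by_group.items():
        means = {
            m: _nanmean([getattr(p, m) for p in members])
            for m in (
                "sensitivity",
                "specificity",
                "ppv",
                "accuracy",
                "gs_count_rel_err",
                "gs_count_rel_abs_err",
                "gs_dur_rel_err",
                "gs_dur_rel_abs_err",
            )
        }
        icc_result: ICCResult | None = None
        if len(members) >= 3:
            mat = np.array([[p.gs_dur_pred_s, p.gs_dur_ref_s] for p in members])
            if np.all(np.isfinite(mat)):
                icc_result = icc_2_1(mat)

        w = weights
        metrics_for_index = dict(means)
        if icc_result is not None and np.isfinite(icc_result.icc):
            metrics_for_index["icc"] = max(icc_result.icc, 0.0)
        elif "icc" in w.weights:
            w = w.without("icc")
        # undefined means: drop the metric and renormalize rather than bias
        for m in list(w.weights):
            if m in metrics_for_index and not np.isfinite(metrics_for_index[m]):
                w = w.without(m)
        index = performance_index(metrics_for_index, w)
        summaries[group] = GroupSummary(
            group=group,
            n=len(members),
            mean_metrics=means,
            icc=icc_result,
            performance_index=index,
        )
    return summaries
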