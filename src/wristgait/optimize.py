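"""Grid-search parameter tuning of registered detectors on labeled corpora."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .algorithms import make_params, run_algorithm
from .evaluation import evaluate_recording
from .simulate import AnnotatedRecording
from .stats import PerfWeights, summarize_group

logger = logging.getLogger(__name__)

__all__ = ["ParamGrid", "grid_search"]

#: Score assigned to parameter combinations on which the detector fails.
FAILURE_SCORE = float("-inf")


@dataclass(frozen=True)
class ParamGrid:
    """Per-parameter candidate values; the cartesian product is enumerated."""

    axes: dict[str, list]

    def __post_init__(self):
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("grid axes must be non-empty")
        object.__setattr__(self, "axes", {k: list(v) for k, v in self.axes.items()})

    @property
    def size(self) -> int:
        n = 1
        for v in self.axes.values():
            n *= len(v)
        return n

    def __iter__(self):
        keys = list(self.axes)
        for combo in itertools.product(*(self.axes[k] for k in keys)):
            yield dict(zip(keys, combo))


def _score(name, combo, corpus, base_bank, weights) -> float:
    params = make_params(name, bank=base_bank, **combo)
    panels = []
    for ar in corpus:
        pred = run_algorithm(name, ar.recording, params=params)
        panels.append(
            evaluate_recording(
                pred,
                ar.truth,
                ar.recording.duration_s,
                subject_id=ar.recording.subject_id,
                group="pooled",
            )
        )
    return summarize_group(panels, weights=weights)["pooled"].performance_index


def grid_search(
    name: str,
    grid: ParamGrid,
    corpus: list[AnnotatedRecording],
    weights: PerfWeights | None = None,
    base_bank: str = "default",
) -> tuple[dict, list[tuple[dict, float]]]:
    """Exhaustively evaluate a parameter grid against an annotated corpus.

    Every combination is scored by the pooled-group performance index;
    detector failures score worst and the run continues.  Returns the best
    combination (deterministic tie-break: first in enumeration order) and
    the full leaderboard for audit.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    logger.info("grid search over %d combinations for %s", grid.size, name)

    leaderboard: list[tuple[dict, float]] = []
    best_combo, best_score = None, FAILURE_SCORE
    for combo in grid:
        try:
            score = _score(name, combo, corpus, base_bank, weights)
        except Exception as exc:  # failed combination scored worst, run continues
            logger.warning("combination %s failed: %s", combo, exc)
            score = FAILURE_SCORE
        leaderboard.append((combo, score))
        if best_combo is None or score > best_score:
            best_combo, best_score = combo, score
    return best_combo, leaderboard
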