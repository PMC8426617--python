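"""Behavioral statistics: set-size RT regression, trials-to-criterion,
plateau performance, learning curves, and weekly aggregation.

Conventions:

* RT means are computed over correct test trials only; timeouts and aborts
  count against accuracy but never enter RT statistics.  Initialization
  trials are excluded from both.
* The learning criterion is a trailing (inclusive) window: the criterion
  trial is the last trial of the first window whose accuracy reaches the
  threshold (default 70% over 10 trials).  Plateau accuracy is the mean of
  outcomes strictly after the criterion trial.
* SEM uses the sample SD (n-1 denominator); a singleton group gets SEM 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SetSizeCell",
    "SearchSessionSummary",
    "SetSizeFit",
    "BlockLearningSummary",
    "WeeklyAggregate",
    "LearningCurve",
    "AnalysisError",
    "search_summary",
    "fit_set_size_regression",
    "trials_to_criterion",
    "plateau_performance",
    "learning_curve",
    "weekly_aggregate",
    "outcomes_by_block",
    "summarize_learning_blocks",
    "session_profile",
]


class AnalysisError(ValueError):
    """Input does not support the requested statistic."""


def _get(record: Any, name: str, default=None):
    if isinstance(record, Mapping):
        return record.get(name, default)
    return getattr(record, name, default)


# ---------------------------------------------------------------------------
# Visual search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SetSizeCell:
    """Per-set-size tallies for one session."""

    mean_rt_s: float | None  # None when no correct trials at this set size
    n_correct: int
    n_total: int


@dataclass(frozen=True)
class SearchSessionSummary:
    per_set_size: dict[int, SetSizeCell]
    accuracy: float
    n_test_trials: int


def search_summary(records: Iterable[Any]) -> SearchSessionSummary:
    """Summarize a session's search test trials.

    ``records`` are trial records (objects or mappings) with fields
    ``task_kind``, ``set_size``, ``outcome`` and ``reaction_time_s``.
    Initialization trials are ignored.
    """
    rts: dict[int, list[float]] = {}
    n_correct: dict[int, int] = {}
    n_total: dict[int, int] = {}
    for rec in records:
        if _get(rec, "task_kind") != "search_test":
            continue
        ss = int(_get(rec, "set_size"))
        outcome = _get(rec, "outcome")
        n_total[ss] = n_total.get(ss, 0) + 1
        if outcome == "correct":
            n_correct[ss] = n_correct.get(ss, 0) + 1
            rts.setdefault(ss, []).append(float(_get(rec, "reaction_time_s")))
    if not n_total:
        raise AnalysisError("log contains no search test trials")
    per = {}
    for ss in sorted(n_total):
        r = rts.get(ss, [])
        per[ss] = SetSizeCell(
            mean_rt_s=float(np.mean(r)) if r else None,
            n_correct=n_correct.get(ss, 0),
            n_total=n_total[ss],
        )
    total = sum(n_total.values())
    correct = sum(n_correct.values())
    return SearchSessionSummary(
        per_set_size=per, accuracy=correct / total, n_test_trials=total
    )


@dataclass(frozen=True)
class SetSizeFit:
    """OLS of mean RT on set size: slope = set-size effect (s/distractor),
    intercept = baseline processing speed (s)."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n_points: int


def fit_set_size_regression(summary: SearchSessionSummary) -> SetSizeFit:
    """Ordinary least squares of per-set-size mean RT on set size."""
    points = [
        (ss, cell.mean_rt_s)
        for ss, cell in summary.per_set_size.items()
        if cell.mean_rt_s is not None
    ]
    if len(points) < 2:
        raise AnalysisError("need at least two set sizes with defined mean RT")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise AnalysisError("all set sizes identical; slope undefined")
    res = stats.linregress(x, y)
    return SetSizeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2),
        n_points=len(points),
    )


# ---------------------------------------------------------------------------
# Learning
# ---------------------------------------------------------------------------

def trials_to_criterion(
    outcomes: Sequence[int], window: int = 10, threshold: float = 0.70
) -> int | None:
    """First (1-based) trial index t >= window at which the trailing-window
    accuracy reaches the threshold; ``None`` when the block is censored
    (criterion never reached, or the block is shorter than the window)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = np.asarray(outcomes, dtype=float)
    if arr.ndim != 1:
        raise ValueError("outcomes must be a 1-D binary sequence")
    if len(arr) < window:
        return None
    csum = np.concatenate([[0.0], np.cumsum(arr)])
    sums = csum[window:] - csum[:-window]  # sums[i] covers trials i+1..i+window
    hits = np.nonzero(sums >= threshold * window - 1e-9)[0]
    if hits.size == 0:
        return None
    return int(hits[0]) + window


def plateau_performance(
    outcomes: Sequence[int], criterion_index: int | None
) -> float | None:
    """Mean accuracy over trials strictly after the criterion trial.

    ``None`` when the criterion trial is the final trial (empty window);
    raises on a censored block.
    """
    if criterion_index is None:
        raise AnalysisError("block is censored; plateau undefined")
    arr = np.asarray(outcomes, dtype=float)
    if not 1 <= criterion_index <= len(arr):
        raise ValueError("criterion index outside the block")
    tail = arr[criterion_index:]
    if tail.size == 0:
        return None
    return float(np.mean(tail))


@dataclass(frozen=True)
class LearningCurve:
    """Per-trial-position mean accuracy with SEM over contributing blocks."""

    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # blocks contributing at each position


def learning_curve(
    blocks: Sequence[Sequence[int]], max_len: int | None = None
) -> LearningCurve:
    """Average outcome at each within-block trial position across blocks.

    Position t pools the blocks whose length is >= t; SEM is over those
    contributing blocks.
    """
    if not blocks:
        raise AnalysisError("need at least one block")
    L = max(len(b) for b in blocks)
    if max_len is not None:
        L = min(L, max_len)
    mean = np.full(L, np.nan)
    sem = np.full(L, np.nan)
    n = np.zeros(L, dtype=int)
    for t in range(L):
        vals = np.array([float(b[t]) for b in blocks if len(b) > t])
        n[t] = vals.size
        if vals.size:
            mean[t] = vals.mean()
            sem[t] = _sem(vals)
    return LearningCurve(mean=mean, sem=sem, n=n)


def _sem(vals: np.ndarray) -> float:
    if vals.size <= 1:
        return 0.0
    return float(np.std(vals, ddof=1) / np.sqrt(vals.size))


@dataclass(frozen=True)
class BlockLearningSummary:
    block_id: int
    trials_to_criterion: int | None
    censored: bool
    plateau_accuracy: float | None
    n_trials: int
    n_varied_dims: int | None = None


def outcomes_by_block(records: Iterable[Any]) -> dict[int, list[int]]:
    """Binary outcome sequence per block from learning-trial records
    (correct = 1; incorrect/timeout/abort = 0)."""
    blocks: dict[int, list[int]] = {}
    for rec in records:
        if _get(rec, "task_kind") != "learning":
            continue
        bid = int(_get(rec, "block_id"))
        blocks.setdefault(bid, []).append(
            1 if _get(rec, "outcome") == "correct" else 0
        )
    return blocks


def summarize_learning_blocks(
    records: Iterable[Any], window: int = 10, threshold: float = 0.70
) -> list[BlockLearningSummary]:
    """Per-block criterion and plateau statistics from a learning trial log."""
    records = list(records)
    blocks = outcomes_by_block(records)
    if not blocks:
        raise AnalysisError("log contains no learning trials")
    varied: dict[int, int | None] = {}
    for rec in records:
        if _get(rec, "task_kind") == "learning":
            vd = _get(rec, "varied_dims")
            varied.setdefault(int(_get(rec, "block_id")), len(vd) if vd else None)
    out = []
    for bid in sorted(blocks):
        seq = blocks[bid]
        ttc = trials_to_criterion(seq, window=window, threshold=threshold)
        plateau = plateau_performance(seq, ttc) if ttc is not None else None
        out.append(
            BlockLearningSummary(
                block_id=bid,
                trials_to_criterion=ttc,
                censored=ttc is None,
                plateau_accuracy=plateau,
                n_trials=len(seq),
                n_varied_dims=varied.get(bid),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Weekly aggregation and profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeeklyAggregate:
    group_index: int
    mean: float
    sem: float
    n: int


def weekly_aggregate(
    per_session_values: Sequence[float], group_size: int = 5
) -> list[WeeklyAggregate]:
    """Pool session values into consecutive non-overlapping groups (default
    five sessions per week); a trailing partial group keeps its own n."""
    vals = [float(v) for v in per_session_values]
    if not vals:
        raise AnalysisError("no session values to aggregate")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    out = []
    for g, start in enumerate(range(0, len(vals), group_size)):
        chunk = np.asarray(vals[start : start + group_size])
        out.append(
            WeeklyAggregate(
                group_index=g,
                mean=float(chunk.mean()),
                sem=_sem(chunk),
                n=int(chunk.size),
            )
        )
    return out


def session_profile(
    records: Iterable[Any], window: int = 10, threshold: float = 0.70
) -> dict:
    """One JSON-ready profile of a session log: search fit (if search trials
    are present) and learning statistics by difficulty (if learning trials
    are present).  Censored blocks are excluded from mean trials-to-criterion.
    """
    records = list(records)
    profile: dict = {}
    if any(_get(r, "task_kind") == "search_test" for r in records):
        summary = search_summary(records)
        profile["search"] = {
            "accuracy": summary.accuracy,
            "n_test_trials": summary.n_test_trials,
            "per_set_size": {
                str(ss): {
                    "mean_rt_s": cell.mean_rt_s,
                    "n_correct": cell.n_correct,
                    "n_total": cell.n_total,
                }
                for ss, cell in summary.per_set_size.items()
            },
        }
        try:
            fit = fit_set_size_regression(summary)
            profile["search"]["fit"] = {
                "slope_s_per_distractor": fit.slope,
                "intercept_s": fit.intercept,
                "slope_se": fit.slope_se,
                "intercept_se": fit.intercept_se,
                "r_squared": fit.r_squared,
            }
        except AnalysisError:
            profile["search"]["fit"] = None
    if any(_get(r, "task_kind") == "learning" for r in records):
        summaries = summarize_learning_blocks(records, window=window, threshold=threshold)
        by_difficulty: dict[str, dict] = {}
        for key in sorted({s.n_varied_dims for s in summaries}, key=lambda k: (k is None, k)):
            subset = [s for s in summaries if s.n_varied_dims == key]
            reached = [s.trials_to_criterion for s in subset if not s.censored]
            plateaus = [
                s.plateau_accuracy for s in subset if s.plateau_accuracy is not None
            ]
            by_difficulty[str(key)] = {
                "n_blocks": len(subset),
                "n_censored": sum(s.censored for s in subset),
                "mean_trials_to_criterion": float(np.mean(reached)) if reached else None,
                "mean_plateau_accuracy": float(np.mean(plateaus)) if plateaus else None,
            }
        n_correct = sum(
            1
            for r in records
            if _get(r, "task_kind") == "learning" and _get(r, "outcome") == "correct"
        )
        n_learning = sum(1 for r in records if _get(r, "task_kind") == "learning")
        profile["learning"] = {
            "n_blocks": len(summaries),
            "accuracy": n_correct / n_learning,
            "criterion_window": window,
            "criterion_threshold": threshold,
            "by_n_varied_dims": by_difficulty,
        }
    if not profile:
        raise AnalysisError("log contains no analyzable trials")
    return profile
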