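"""RT-distribution descriptors: quantiles, delta plots, CAFs.

Conflict-task analyses summarize each congruency condition by the RT
quantiles of correct responses and the accuracy rate, then contrast
conditions with two standard displays:

* the *delta plot* — the per-quantile RT difference (incongruent minus
  congruent) against the mean of the two conditions' quantiles; its
  slope sign separates flanker-like (positive) from Simon-like
  (negative) dynamics;
* the *conditional accuracy function* (CAF) — accuracy within
  equal-count RT bins from fastest to slowest responses.

Group-level distributions are formed by quantile averaging: per-subject
quantiles at matched probabilities, averaged arithmetically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import TrialTable

__all__ = [
    "PROBS_DEFAULT",
    "ConditionSummary",
    "DeltaPlot",
    "CAF",
    "apply_exclusions",
    "rt_quantiles",
    "condition_summary",
    "delta_plot",
    "delta_slope",
    "caf",
    "group_quantile_average",
]

log = logging.getLogger(__name__)

#: Quantile probabilities used throughout: the conventional five levels.
PROBS_DEFAULT = (0.1, 0.3, 0.5, 0.7, 0.9)

#: RT exclusion window (ms), inclusive at both ends: trials *shorter
#: than* 200 ms or *longer than* 1200 ms are dropped.
MIN_RT_DEFAULT = 200.0
MAX_RT_DEFAULT = 1200.0


@dataclass(frozen=True)
class ConditionSummary:
    """Quantiles, accuracy and counts for one congruency condition."""

    probs: tuple
    quantiles: tuple          # RT (ms) of correct trials at `probs`
    accuracy: float
    n_total: int
    n_correct: int

    def __post_init__(self):
        q = np.asarray(self.quantiles)
        if np.any(np.diff(q) < 0):
            raise ValueError("quantiles must be non-decreasing")
        if not 0.0 <= self.accuracy <= 1.0 or self.n_correct > self.n_total:
            raise ValueError("inconsistent accuracy/counts")


@dataclass(frozen=True)
class DeltaPlot:
    """Per-quantile (x, delta) pairs; delta = incongruent - congruent RT."""

    probs: tuple
    x: tuple                  # mean of the two conditions' RT (ms)
    delta: tuple              # incongruent - congruent (ms)
    mode: str = "quantile"    # 'quantile' or 'bin-mean'


@dataclass(frozen=True)
class CAF:
    """Accuracy per equal-count RT bin, one sequence per condition."""

    n_bins: int
    accuracy: dict            # condition label -> tuple of bin accuracies
    bin_counts: dict          # condition label -> tuple of bin sizes


def apply_exclusions(trials: TrialTable,
                     min_rt: float = MIN_RT_DEFAULT,
                     max_rt: float = MAX_RT_DEFAULT) -> TrialTable:
    """Keep trials with ``min_rt <= rt_ms <= max_rt`` (bounds inclusive)."""
    df = trials.data
    keep = (df["rt_ms"] >= min_rt) & (df["rt_ms"] <= max_rt)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("excluded %d of %d trials outside [%g, %g] ms",
                 n_dropped, len(df), min_rt, max_rt)
    out = df[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("all trials excluded by the RT window")
    meta = dict(trials.meta, exclusions={"min_rt": min_rt, "max_rt": max_rt,
                                         "n_dropped": n_dropped})
    return TrialTable(out, meta)


def rt_quantiles(rts, probs=PROBS_DEFAULT) -> np.ndarray:
    """Linear-interpolation order-statistic quantiles of the RTs."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        raise ValueError(f"need at least 2 observations, got {rts.size}")
    return np.quantile(rts, probs, method="linear")


def condition_summary(cond_trials: pd.DataFrame,
                      probs=PROBS_DEFAULT) -> ConditionSummary:
    """Summarize one condition: correct-RT quantiles, accuracy, counts."""
    correct = cond_trials[cond_trials["accuracy"] == 1]
    q = rt_quantiles(correct["rt_ms"].to_numpy(), probs)
    return ConditionSummary(
        probs=tuple(probs), quantiles=tuple(q.tolist()),
        accuracy=float(cond_trials["accuracy"].mean()),
        n_total=len(cond_trials), n_correct=len(correct))


def _bin_means(rts: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean RT within equal-count bins of the sorted sample."""
    order = np.sort(rts)
    splits = _equal_count_splits(order.size, n_bins)
    return np.array([chunk.mean() for chunk in np.split(order, splits)])


def delta_plot(cong: ConditionSummary, incong: ConditionSummary,
               mode: str = "quantile",
               cong_rts=None, incong_rts=None) -> DeltaPlot:
    """Delta plot from two condition summaries.

    In 'quantile' mode each point is (mean of quantiles, difference of
    quantiles) at one probability level.  In 'bin-mean' mode the RT
    values are the mean correct RT within five equal-count bins, which
    requires the raw correct RTs of both conditions.
    """
    if cong.probs != incong.probs:
        raise ValueError("probability levels differ between conditions")
    if mode == "quantile":
        qc = np.asarray(cong.quantiles)
        qi = np.asarray(incong.quantiles)
    elif mode == "bin-mean":
        if cong_rts is None or incong_rts is None:
            raise ValueError("bin-mean mode needs the raw correct RTs")
        n_bins = len(cong.probs)
        qc = _bin_means(np.asarray(cong_rts, float), n_bins)
        qi = _bin_means(np.asarray(incong_rts, float), n_bins)
    else:
        raise ValueError(f"unknown delta-plot mode {mode!r}")
    return DeltaPlot(probs=cong.probs,
                     x=tuple(((qc + qi) / 2.0).tolist()),
                     delta=tuple((qi - qc).tolist()),
                     mode=mode)


def delta_plot_from_table(trials: TrialTable, mode: str = "quantile",
                          probs=PROBS_DEFAULT) -> DeltaPlot:
    """Convenience: delta plot straight from a two-condition trial table."""
    cong_df = trials.condition("congruent")
    incong_df = trials.condition("incongruent")
    cs = condition_summary(cong_df, probs)
    ics = condition_summary(incong_df, probs)
    return delta_plot(
        cs, ics, mode,
        cong_rts=cong_df.loc[cong_df["accuracy"] == 1, "rt_ms"].to_numpy(),
        incong_rts=incong_df.loc[incong_df["accuracy"] == 1, "rt_ms"].to_numpy())


def delta_slope(dp: DeltaPlot) -> float:
    """Ordinary least-squares slope of delta against x (unitless)."""
    x = np.asarray(dp.x)
    d = np.asarray(dp.delta)
    if x.size < 2:
        raise ValueError("need at least 2 delta-plot points")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate x spread; slope undefined")
    return float(np.polyfit(x, d, 1)[0])


def delta_sign(dp: DeltaPlot) -> int:
    """Secondary classifier: sign of (last - first) delta."""
    return int(np.sign(dp.delta[-1] - dp.delta[0]))


def _equal_count_splits(n: int, n_bins: int) -> np.ndarray:
    """Split points for equal-count bins; remainders go to earlier bins."""
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    return np.cumsum(sizes)[:-1]


def caf(cond_trials: pd.DataFrame, n_bins: int = 5):
    """Conditional accuracy function for one condition.

    All trials (correct and error) are sorted by RT and split into
    ``n_bins`` equal-count bins — remainder trials go to the earliest
    (fastest) bins — and accuracy is computed per bin.  Returns
    (accuracies, bin sizes).
    """
    n = len(cond_trials)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} trials, got {n}")
    order = cond_trials.sort_values("rt_ms", kind="mergesort")
    acc = order["accuracy"].to_numpy(float)
    splits = _equal_count_splits(n, n_bins)
    chunks = np.split(acc, splits)
    return (np.array([c.mean() for c in chunks]),
            np.array([c.size for c in chunks]))


def caf_from_table(trials: TrialTable, n_bins: int = 5) -> CAF:
    """CAF for both congruency conditions of a trial table."""
    accuracy, counts = {}, {}
    for cond in ("congruent", "incongruent"):
        a, c = caf(trials.condition(cond), n_bins)
        accuracy[cond] = tuple(a.tolist())
        counts[cond] = tuple(int(x) for x in c)
    return CAF(n_bins=n_bins, accuracy=accuracy, bin_counts=counts)


def group_quantile_average(summaries) -> ConditionSummary:
    """Average per-subject condition summaries at matched probabilities.

    RT quantiles are averaged arithmetically per probability level;
    accuracy is the unweighted mean across subjects.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to average")
    probs = summaries[0].probs
    if any(s.probs != probs for s in summaries):
        raise ValueError("probability levels differ across subjects")
    q = np.mean([s.quantiles for s in summaries], axis=0)
    return ConditionSummary(
        probs=probs, quantiles=tuple(q.tolist()),
        accuracy=float(np.mean([s.accuracy for s in summaries])),
        n_total=int(sum(s.n_total for s in summaries)),
        n_correct=int(sum(s.n_correct for s in summaries)))
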