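"""Behavioral summaries: condition RT means, errors, inhibition scores.

The inhibition score is the mean RT of the inhibition condition minus
the neutral condition (incongruent-congruent, np-control,
incompatible-compatible), computed over correct trials only; omissions
count as errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tasks import CONDITIONS, Task

__all__ = ["BehaviorSummary", "summarize_behavior", "paired_effect_test"]


class InsufficientBehaviorError(ValueError):
    pass


@dataclass(frozen=True)
class BehaviorSummary:
    task: Task
    mean_rt: dict  # condition -> mean RT (s) over correct trials
    error_count: dict  # condition -> errors (incl. omissions)
    trial_count: dict  # condition -> total trials
    inhibition_score: float  # seconds


def summarize_behavior(trials) -> BehaviorSummary:
    """Summarize one subject/phase/task trial list.

    Raises :class:`InsufficientBehaviorError` if any condition has zero
    correct trials (its mean RT would be undefined).
    """
    trials = list(trials)
    if not trials:
        raise InsufficientBehaviorError("no trials to summarize")
    task = trials[0].task
    inhib_cond, neutral_cond = CONDITIONS[task]

    mean_rt, error_count, trial_count = {}, {}, {}
    for cond in (neutral_cond, inhib_cond):
        sub = [t for t in trials if t.condition == cond]
        correct_rts = [t.rt for t in sub if t.correct and math.isfinite(t.rt)]
        trial_count[cond] = len(sub)
        error_count[cond] = sum(1 for t in sub if not t.correct)
        if not correct_rts:
            raise InsufficientBehaviorError(
                f"no correct trials in condition {cond!r}: mean RT undefined"
            )
        mean_rt[cond] = float(np.mean(correct_rts))
    return BehaviorSummary(
        task=task,
        mean_rt=mean_rt,
        error_count=error_count,
        trial_count=trial_count,
        inhibition_score=mean_rt[inhib_cond] - mean_rt[neutral_cond],
    )


def paired_effect_test(values_a, values_b) -> tuple[float, int, float]:
    """Paired t-test: returns (t, df, two-sided p) with df = n - 1."""
    from scipy import stats

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-d and of equal length (paired)")
    n = a.size
    if n < 2:
        raise ValueError("paired test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, n - 1, 1.0
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)
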