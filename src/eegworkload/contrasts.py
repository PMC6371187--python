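"""Planned-contrast statistics for pre/post training gains.

Baseline one-way ANOVA, joint regression of per-subject gains
(post - pre) on two orthogonal contrast codes —

* ``ABxC`` (both trainings vs control): A = +1, B = +1, C = -2
* ``AxB``  (simulator vs attention):    A = +1, B = -1, C =  0

— with one-tailed p in the hypothesized direction (training reduces
the outcome, so negative coefficients), and a repeated-measures
Cohen's d that rescales the change-score effect to the
independent-groups metric via the pre-post correlation r:

    d = (M_pre - M_post) * sqrt(2 (1 - r))
        / sqrt(SD_pre² + SD_post² - 2 r SD_pre SD_post)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tasks import Task

logger = logging.getLogger(__name__)

__all__ = [
    "GainRecord",
    "ContrastResult",
    "EffectSize",
    "CONTRAST_CODES",
    "baseline_anova",
    "planned_contrast_regression",
    "morris_deshon_d",
    "build_report",
]

GROUP_ORDER = ("A", "B", "C")
#: orthogonal contrast weights per group
CONTRAST_CODES = {
    "ABxC": {"A": 1.0, "B": 1.0, "C": -2.0},
    "AxB": {"A": 1.0, "B": -1.0, "C": 0.0},
}


@dataclass(frozen=True)
class GainRecord:
    subject: int
    group: str
    task: Task
    outcome: str  # 'tar' | 'inhibition_score'
    gain: float  # post - pre

    def __post_init__(self) -> None:
        if self.group not in GROUP_ORDER:
            raise ValueError(f"invalid group label {self.group!r}")


@dataclass(frozen=True)
class ContrastResult:
    name: str
    B: float
    SE: float
    beta: float
    F: float
    df: int
    p: float  # one-tailed, hypothesized (negative) direction

    @property
    def t(self) -> float:
        return self.B / self.SE if self.SE > 0 else 0.0


@dataclass(frozen=True)
class EffectSize:
    d: float
    m_pre: float
    m_post: float
    sd_pre: float
    sd_post: float
    r: float


def baseline_anova(values, groups) -> tuple[float, int, int, float]:
    """One-way ANOVA of baseline values: (F, df_between, df_within, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    chunks = [values[groups == g] for g in labels]
    for g, c in zip(labels, chunks):
        if c.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    n, k = values.size, len(labels)
    grand = values.mean()
    ss_between = sum(c.size * (c.mean() - grand) ** 2 for c in chunks)
    ss_within = sum(((c - c.mean()) ** 2).sum() for c in chunks)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        raise ValueError("zero within-group variance: F undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def planned_contrast_regression(gains) -> dict[str, ContrastResult]:
    """Joint OLS of gains on both contrast codes plus intercept.

    Returns ``{'ABxC': ..., 'AxB': ...}``.  Per contrast: unstandardized
    B with its SE, standardized beta, F = t² on (1, n - 3) df, and the
    one-tailed p for the directional hypothesis (coefficient < 0).
    Degenerate inputs with zero residual variance return B = 0 and
    p = 0.5 instead of dividing by zero.
    """
    gains = list(gains)
    groups = np.array([g.group for g in gains])
    y = np.array([g.gain for g in gains], dtype=float)
    present = set(groups)
    missing = [g for g in GROUP_ORDER if g not in present]
    if missing:
        raise ValueError(f"empty group(s): {missing}; all of A, B, C required")
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 records for a residual df > 0")

    names = list(CONTRAST_CODES)
    if np.ptp(y) == 0:  # constant gains: no signal, no residual variance
        return {name: ContrastResult(name, 0.0, 0.0, 0.0, 0.0, n - 3, 0.5) for name in names}
    X = np.column_stack(
        [np.ones(n)]
        + [np.array([CONTRAST_CODES[c][g] for g in groups]) for c in names]
    )
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("degenerate design: contrast codes collinear")
    resid = y - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    sd_y = y.std(ddof=1)

    results = {}
    for j, name in enumerate(names, start=1):
        b = float(coef[j])
        se = float(np.sqrt(cov[j, j]))
        if se == 0 or not np.isfinite(se):
            results[name] = ContrastResult(name, 0.0, 0.0, 0.0, 0.0, df, 0.5)
            continue
        t = b / se
        x_col = X[:, j]
        beta = b * x_col.std(ddof=1) / sd_y if sd_y > 0 else 0.0
        # directional hypothesis: training lowers the outcome (b < 0)
        p = float(stats.t.cdf(t, df))
        results[name] = ContrastResult(name, b, se, float(beta), float(t * t), df, p)
    return results


def morris_deshon_d(
    m_pre: float, m_post: float, sd_pre: float, sd_post: float, r: float
) -> EffectSize:
    """Repeated-measures Cohen's d in the independent-groups metric."""
    if sd_pre <= 0 or sd_post <= 0:
        raise ValueError("SDs must be positive")
    if not -1 < r < 1:
        raise ValueError("r must lie in (-1, 1)")
    denom2 = sd_pre**2 + sd_post**2 - 2 * r * sd_pre * sd_post
    if denom2 <= 0:
        raise ValueError("zero change-score variance: d undefined")
    d = (m_pre - m_post) * np.sqrt(2 * (1 - r)) / np.sqrt(denom2)
    return EffectSize(float(d), m_pre, m_post, sd_pre, sd_post, r)


# --- report assembly -------------------------------------------------------

_SIG_LEVELS = ((0.01, "**"), (0.05, "*"), (0.10, "+"))


def _sig_marker(p: float) -> str:
    for level, marker in _SIG_LEVELS:
        if p < level:
            return marker
    return ""


def build_report(scores: pd.DataFrame, r: float = 0.7) -> dict[str, pd.DataFrame]:
    """Descriptive, contrast and figure-data tables from a cohort frame.

    ``scores`` must have columns ``subject, group, task, tar_pre,
    tar_post, inhib_pre, inhib_post`` (one row per subject x task).
    Returns ``{'table1': ..., 'table2': ..., 'figure3_data': ...}``;
    the contrast table is suppressed (``None``) with a warning when
    fewer than three groups are present.
    """
    required = {"subject", "group", "task", "tar_pre", "tar_post"}
    if scores is None or scores.empty:
        raise ValueError("empty cohort: nothing to report")
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"scores frame missing columns: {sorted(missing)}")

    outcomes = [("tar", "tar_pre", "tar_post")]
    if {"inhib_pre", "inhib_post"} <= set(scores.columns):
        outcomes.append(("inhibition_score", "inhib_pre", "inhib_post"))

    t1_rows = []
    for task in scores["task"].unique():
        sub_t = scores[scores["task"] == task]
        for outcome, pre_col, post_col in outcomes:
            for group in GROUP_ORDER:
                cell = sub_t[sub_t["group"] == group]
                if cell.empty:
                    logger.warning("no data for group %s task %s", group, task)
                    t1_rows.append([task, outcome, group] + [np.nan] * 5 + ["NA"])
                    continue
                m_pre, s_pre = cell[pre_col].mean(), cell[pre_col].std(ddof=1)
                m_post, s_post = cell[post_col].mean(), cell[post_col].std(ddof=1)
                try:
                    d = morris_deshon_d(m_pre, m_post, s_pre, s_post, r).d
                except ValueError:
                    d = np.nan
                t1_rows.append(
                    [task, outcome, group, m_pre, s_pre, m_post, s_post, d,
                     f"{m_pre:.3f} ({s_pre:.3f}) -> {m_post:.3f} ({s_post:.3f})"]
                )
    table1 = pd.DataFrame(
        t1_rows,
        columns=["task", "outcome", "group", "mean_pre", "sd_pre",
                 "mean_post", "sd_post", "d", "formatted"],
    )

    table2 = None
    if set(scores["group"].unique()) >= set(GROUP_ORDER):
        t2_rows = []
        for task in scores["task"].unique():
            sub_t = scores[scores["task"] == task]
            for outcome, pre_col, post_col in outcomes:
                gains = [
                    GainRecord(int(row.subject), str(row.group), Task(task),
                               outcome, float(getattr(row, post_col) - getattr(row, pre_col)))
                    for row in sub_t.itertuples()
                ]
                for name, res in planned_contrast_regression(gains).items():
                    t2_rows.append(
                        [task, outcome, name, res.B, res.SE, res.beta,
                         res.F, res.df, res.p, _sig_marker(res.p)]
                    )
        table2 = pd.DataFrame(
            t2_rows,
            columns=["task", "outcome", "contrast", "B", "SE", "beta",
                     "F", "df", "p_one_tailed", "sig"],
        )
    else:
        warnings.warn("fewer than three groups present: contrast table suppressed")

    f3_rows = []
    for task in scores["task"].unique():
        sub_t = scores[scores["task"] == task]
        for group in GROUP_ORDER:
            cell = sub_t[sub_t["group"] == group]
            if cell.empty:
                continue
            for phase, col in (("pre", "tar_pre"), ("post", "tar_post")):
                f3_rows.append(
                    [task, group, phase, cell[col].mean(),
                     cell[col].std(ddof=1) / np.sqrt(len(cell))]
                )
    figure3 = pd.DataFrame(f3_rows, columns=["task", "group", "phase", "mean", "sem"])

    return {"table1": table1, "table2": table2, "figure3_data": figure3}
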