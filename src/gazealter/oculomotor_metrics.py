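"""Per-trial oculomotor/head summary metrics and between-condition statistics.

Metrics follow the standard reduction for free-viewing tasks: saccade rate
(events/s, saccade count over task duration), median saccade amplitude
(deg), median fixation duration (ms), and total head rotation — the sum of
Euclidean norms of consecutive Euler-angle deltas,

    HR = sum_i sqrt((a_i - a_{i+1})^2 + (b_i - b_{i+1})^2 + (g_i - g_{i+1})^2),

computed on unwrapped angle series so a 359 deg -> 1 deg representation
jump contributes 2 deg of movement, not 358.

Conditions are compared with a Friedman rank ANOVA (computed here from
within-subject ranks, mean ranks on ties, with tie correction) followed by
post-hoc pairwise comparisons on mean ranks: the Nemenyi studentized-range
procedure (the Tukey analogue for this design) by default, with the more
powerful Conover t-procedure as an option.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import EventTableRow, HeadLogRecord

CONDITIONS = ("N", "B", "H", "T")


class IncompleteDesignError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class TaskMetrics:
    """Per-trial summary; median fields are None when no event of that kind exists."""

    condition: str
    task_duration_s: float
    saccade_rate_eps: float
    median_saccade_amplitude_deg: float | None
    median_fixation_duration_ms: float | None
    total_head_rotation_deg: float
    n_saccades: int
    n_fixations: int


@dataclasses.dataclass(frozen=True)
class ConditionComparison:
    statistic: float
    p_value: float
    conditions: tuple[str, ...]
    pairwise: np.ndarray  # corrected p-values, symmetric, unit diagonal

    def __post_init__(self):
        p = np.asarray(self.pairwise, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("pairwise must be a square matrix")


def saccade_rate(n_saccades: int, task_duration_s: float) -> float:
    """Saccades per second: event count divided by task duration."""
    if task_duration_s <= 0:
        raise ValueError("task duration must be positive")
    return n_saccades / task_duration_s


def _unwrap_deg(series: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(series), axis=0))


def head_rotation_total(orientations: Sequence[HeadLogRecord] | np.ndarray) -> float:
    """Total head rotation (deg): summed norms of consecutive Euler deltas.

    Accepts HeadLogRecord sequences or an (n, 3) array of (alpha, beta,
    gamma) in degrees.  Each angle series is unwrapped before differencing
    so representation wrap-arounds do not count as movement.
    """
    if len(orientations) == 0:
        raise ValueError("need at least one head sample")
    if isinstance(orientations[0], HeadLogRecord):
        ang = np.array([o.orientation_deg for o in orientations], dtype=float)
    else:
        ang = np.asarray(orientations, dtype=float).reshape(len(orientations), 3)
    if len(ang) < 2:
        return 0.0
    deltas = np.diff(_unwrap_deg(ang), axis=0)
    return float(np.sum(np.linalg.norm(deltas, axis=1)))


def summarize_trial(events: Sequence[EventTableRow],
                    head: Sequence[HeadLogRecord] | np.ndarray,
                    condition: str, task_duration_s: float) -> TaskMetrics:
    """Reduce one trial's events and head trace to its summary metrics."""
    if task_duration_s <= 0:
        raise ValueError("task duration must be positive")
    saccades = [e for e in events if e.event_type == "saccade"]
    fixations = [e for e in events if e.event_type == "fixation"]
    amp = (float(np.median([e.amplitude_deg for e in saccades]))
           if saccades else None)
    fix = (float(np.median([e.duration_ms for e in fixations]))
           if fixations else None)
    return TaskMetrics(
        condition=condition,
        task_duration_s=task_duration_s,
        saccade_rate_eps=saccade_rate(len(saccades), task_duration_s),
        median_saccade_amplitude_deg=amp,
        median_fixation_duration_ms=fix,
        total_head_rotation_deg=head_rotation_total(head) if len(head) else 0.0,
        n_saccades=len(saccades),
        n_fixations=len(fixations),
    )


def metrics_frame(metrics: Sequence[TaskMetrics], **extra) -> pd.DataFrame:
    """Tidy one-row-per-trial DataFrame of TaskMetrics (for CSV export)."""
    frame = pd.DataFrame([dataclasses.asdict(m) for m in metrics])
    for key, val in extra.items():
        frame[key] = val
    return frame


def _check_matrix(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise IncompleteDesignError("need a subjects x conditions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise IncompleteDesignError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(x)):
        raise IncompleteDesignError("matrix contains missing cells")
    return x


def _row_ranks(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, x)


def friedman_test(values, conditions: Sequence[str] | None = None,
                  posthoc: str | None = "nemenyi") -> ConditionComparison:
    """Friedman rank ANOVA over a subjects x conditions matrix.

    Each subject's row is ranked (mean ranks on ties); the chi-square
    statistic, with tie correction, is referred to a chi-square
    distribution with k-1 degrees of freedom.  Post-hoc pairwise p-values
    are attached (see :func:`posthoc_pairwise`) unless ``posthoc`` is None.
    """
    x = _check_matrix(values)
    n, k = x.shape
    ranks = _row_ranks(x)
    colsum = ranks.sum(axis=0)
    statistic = (12.0 / (n * k * (k + 1))) * np.sum(colsum ** 2) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - ties / (n * k * (k * k - 1))
    if correction > 0:
        statistic /= correction
    else:
        statistic = 0.0  # every row entirely tied
    p = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0
    if conditions is None:
        conditions = tuple(f"C{i}" for i in range(k))
    pair = np.ones((k, k)) if posthoc is None else posthoc_pairwise(x, method=posthoc)
    return ConditionComparison(statistic=float(max(statistic, 0.0)), p_value=p,
                               conditions=tuple(conditions), pairwise=pair)


def posthoc_pairwise(values, method: str = "nemenyi") -> np.ndarray:
    """All-pairs post-hoc comparisons after a Friedman test, on mean ranks.

    ``nemenyi`` (default): studentized-range test on rank sums, the
    standard Tukey-family correction for this design.  ``conover``:
    t-statistics on rank sums with the Friedman-adjusted pooled variance,
    Holm-corrected.  Returns a symmetric matrix with unit diagonal.
    """
    x = _check_matrix(values)
    n, k = x.shape
    ranks = _row_ranks(x)
    rsum = ranks.sum(axis=0)
    out = np.ones((k, k))

    if method == "nemenyi":
        # q = |R_i - R_j| / sqrt(n k (k+1) / 12), referred to the
        # studentized range with k groups, infinite df
        denom = math.sqrt(n * k * (k + 1) / 12.0)
        for i in range(k):
            for j in range(i + 1, k):
                q = abs(rsum[i] - rsum[j]) / denom
                p = float(stats.studentized_range.sf(q, k, np.inf))
                out[i, j] = out[j, i] = min(1.0, p)
    elif method == "conover":
        stat, _, _, _ = _friedman_parts(x, ranks)
        a = float(np.sum(ranks ** 2))
        b = n * k * (k + 1) ** 2 / 4.0
        df = (n - 1) * (k - 1)
        denom_sq = 2.0 * n * (1.0 - stat / (n * (k - 1))) * (a - b) / df
        denom = math.sqrt(max(denom_sq, np.finfo(float).tiny))
        raw = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                tval = abs(rsum[i] - rsum[j]) / denom
                raw[i, j] = raw[j, i] = 2.0 * float(stats.t.sf(tval, df))
        out = _holm(raw)
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return out


def _friedman_parts(x: np.ndarray, ranks: np.ndarray):
    n, k = x.shape
    colsum = ranks.sum(axis=0)
    stat = (12.0 / (n * k * (k + 1))) * np.sum(colsum ** 2) - 3.0 * n * (k + 1)
    return stat, colsum, n, k


def _holm(raw: np.ndarray) -> np.ndarray:
    k = raw.shape[0]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    pvals = np.array([raw[i, j] for i, j in pairs])
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    out = np.ones((k, k))
    for (i, j), p in zip(pairs, adj):
        out[i, j] = out[j, i] = p
    return out
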