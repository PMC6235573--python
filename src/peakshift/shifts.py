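"""Percent-change shift metrics and planned-comparison t-tests.

Shifts between training and test are expressed per subject as
100·(test − train)/train for a measure (peak time, start, stop, or CV), and
summarized with a one-sample t-test of the percent changes against zero.
Between-group planned comparisons use the pooled-variance two-sample t.
Omnibus ANOVA is deliberately out of scope: the tidy shift table this module
emits feeds standard statistical tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

MEASURES = ("peak_time", "start", "stop", "cv")


@dataclass
class ShiftSummary:
    """Per-subject percent changes with the one-sample t against zero."""

    group: str
    measure: str
    subjects: list[str]
    pct_changes: np.ndarray
    mean: float
    sem: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def percent_change(train_value: float, test_value: float) -> float:
    """100·(test − train)/train; the baseline must be positive."""
    if train_value <= 0:
        raise ValueError("percent change needs a positive baseline")
    return 100.0 * (test_value - train_value) / train_value


def group_shift_summary(
    train_values: Sequence[float],
    test_values: Sequence[float],
    group: str = "",
    measure: str = "peak_time",
    subjects: Optional[Sequence[str]] = None,
) -> ShiftSummary:
    """Summarize within-group shifts: mean ± SEM and paired-structure t.

    The t statistic is the one-sample t of the per-subject percent changes
    against 0 (df = n − 1), the planned-comparison structure for "did this
    group shift?".  Zero variance is flagged degenerate: t = ±inf, p = 0
    for a nonzero mean; t = 0, p = 1 when every change is exactly zero.
    """
    train = np.asarray(train_values, dtype=float)
    test = np.asarray(test_values, dtype=float)
    if train.shape != test.shape or train.size < 2:
        raise ValueError("need matched train/test values for at least 2 subjects")
    changes = np.array([percent_change(a, b) for a, b in zip(train, test)])
    if not np.all(np.isfinite(changes)):
        raise ValueError("non-finite percent change")
    n = changes.size
    mean = float(changes.mean())
    sd = float(changes.std(ddof=1))
    sem = sd / np.sqrt(n)
    if sd == 0.0:
        t = np.inf * np.sign(mean) if mean != 0 else 0.0
        p = 0.0 if mean != 0 else 1.0
        degenerate = True
    else:
        t, p = stats.ttest_1samp(changes, 0.0)
        t, p = float(t), float(p)
        degenerate = False
    subjects = list(subjects) if subjects is not None else [
        f"s{i + 1:02d}" for i in range(n)
    ]
    return ShiftSummary(
        group=group, measure=measure, subjects=subjects, pct_changes=changes,
        mean=mean, sem=float(sem), t=t, df=n - 1, p=p, degenerate=degenerate,
    )


def between_group_compare(a: ShiftSummary, b: ShiftSummary) -> tuple[float, int, float]:
    """Pooled-variance independent-samples t on the two groups' percent changes.

    Returns (t, df, p) with df = n_a + n_b − 2.
    """
    xa, xb = a.pct_changes, b.pct_changes
    na, nb = xa.size, xb.size
    if na < 2 or nb < 2:
        raise ValueError("both groups need n >= 2")
    df = na + nb - 2
    sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / df
    if sp2 == 0.0:
        if xa.mean() == xb.mean():
            return 0.0, df, 1.0
        raise ValueError("degenerate pooled variance with unequal means")
    t = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)
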