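"""Break-run-break change-point fits for individual probe trials.

Within a single probe trial responding is modeled as three flat rate
segments — low, high, low.  The fit places the two change points (start s,
stop e) at response times and maximizes

    I(s, e) = d1·(r − r1) + d2·(r2 − r) + d3·(r − r3)

where segment i has duration d_i and rate r_i (counts/duration, 0 for
zero-duration segments) over [0, s), [s, e], (e, T], and r = n/T is the
overall rate.  Boundary responses at s or e belong to the middle segment.
The exhaustive search over all response-time pairs is small (trials carry
tens of responses) and ties are broken toward the smallest s, then the
smallest e, so the output is deterministic.

Trial-validity filters annotate rather than drop: a fit is ``valid`` only if
the trial has enough responses, the run straddles the session peak time,
and (when configured) the first response beats the early-response cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import TrialKey, TrialRecord

EXCLUSION_REASONS = (
    "too_few_responses",
    "start_not_before_peak",
    "stop_not_after_peak",
    "early_response_cutoff",
)


@dataclass
class SingleTrialFit:
    """Start/stop change points and segment rates for one probe trial."""

    key: TrialKey
    cue_id: str
    start: float
    stop: float
    r1: float
    r2: float
    r3: float
    index: float
    n_responses: int
    first_response: Optional[float]
    trial_duration: float
    valid: bool = False
    exclusion_reasons: list[str] = field(default_factory=list)


@dataclass
class FilterRules:
    """Validity rules applied to single-trial fits.

    ``session_peak_time`` is the peak time of the matching session-average
    fit; a valid run must start before it and stop after it.
    """

    min_responses: int = 3
    straddle_peak: bool = True
    session_peak_time: Optional[float] = None
    early_response_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_responses < 1:
            raise ValueError("min_responses must be >= 1")


def lhl_objective(times: np.ndarray, T: float, s: float, e: float) -> float:
    """Recompute I(s, e) for given change points (shared with the search)."""
    times = np.asarray(times, dtype=float)
    n = times.size
    r = n / T
    c1 = int(np.sum(times < s))
    c2 = int(np.sum((times >= s) & (times <= e)))
    c3 = n - c1 - c2
    d1, d2, d3 = s, e - s, T - e
    r1 = c1 / d1 if d1 > 0 else 0.0
    r2 = c2 / d2 if d2 > 0 else 0.0
    r3 = c3 / d3 if d3 > 0 else 0.0
    return d1 * (r - r1) + d2 * (r2 - r) + d3 * (r - r3)


class LowHighLowSegmenter(BaseEstimator):
    """sklearn-style change-point estimator for one trial's response times.

    ``fit(X)`` takes the response timestamps (n,) or (n, 1); the trial
    duration is passed at construction.  Fitted attributes: ``start_``,
    ``stop_``, ``rates_`` (r1, r2, r3) and ``index_``.
    """

    def __init__(self, trial_duration: float = 1.0):
        self.trial_duration = trial_duration

    def fit(self, X, y=None):
        t = np.sort(np.asarray(X, dtype=float).ravel())
        T = float(self.trial_duration)
        if t.size == 0:
            raise ValueError("cannot segment a trial with zero responses")
        if T <= 0 or (t.size and t[-1] > T + 1e-9):
            raise ValueError("responses must lie within (0, trial_duration]")

        n = t.size
        r = n / T
        cand = np.unique(t)
        m = cand.size
        # counts below/above each candidate via searchsorted
        below = np.searchsorted(t, cand, side="left")        # t < cand
        upto = np.searchsorted(t, cand, side="right")        # t <= cand

        s = cand[:, None]
        e = cand[None, :]
        c1 = below[:, None].astype(float)
        c2 = (upto[None, :] - below[:, None]).astype(float)
        c3 = n - c1 - c2
        d1 = s
        d2 = e - s
        d3 = T - e
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = np.where(d1 > 0, c1 / np.where(d1 > 0, d1, 1.0), 0.0)
            r2 = np.where(d2 > 0, c2 / np.where(d2 > 0, d2, 1.0), 0.0)
            r3 = np.where(d3 > 0, c3 / np.where(d3 > 0, d3, 1.0), 0.0)
        obj = d1 * (r - r1) + d2 * (r2 - r) + d3 * (r - r3)
        obj = np.where(s <= e, obj, -np.inf)  # upper triangle only

        # argmax in row-major order = smallest s first, then smallest e
        flat = int(np.argmax(obj))
        i, j = divmod(flat, m)
        self.start_ = float(cand[i])
        self.stop_ = float(cand[j])
        self.rates_ = (float(r1[i, 0]), float(r2[i, j]), float(r3[i, j]))
        self.index_ = float(obj[i, j])
        self.n_features_in_ = 1
        return self


def fit_low_high_low(trial: TrialRecord) -> SingleTrialFit:
    """Fit the three-flat-line model to one probe trial.

    Raises for non-probe trials and zero responses.  A single-response trial
    yields a degenerate (s = e) fit that the filters always mark invalid.
    """
    if trial.trial_type != "probe":
        raise ValueError("single-trial fits are defined for probe trials only")
    if trial.n_responses == 0:
        raise ValueError("cannot fit a trial with zero responses")

    seg = LowHighLowSegmenter(trial_duration=trial.trial_end).fit(trial.responses)
    return SingleTrialFit(
        key=trial.key,
        cue_id=trial.cue_id,
        start=seg.start_,
        stop=seg.stop_,
        r1=seg.rates_[0],
        r2=seg.rates_[1],
        r3=seg.rates_[2],
        index=seg.index_,
        n_responses=trial.n_responses,
        first_response=trial.first_response,
        trial_duration=trial.trial_end,
    )


def apply_trial_filters(
    fits: Iterable[SingleTrialFit], rules: FilterRules
) -> list[SingleTrialFit]:
    """Annotate each fit with validity and exclusion reasons (drops nothing)."""
    if rules.straddle_peak and rules.session_peak_time is None:
        raise ValueError("straddle_peak filter needs session_peak_time")
    out = []
    for f in fits:
        reasons: list[str] = []
        if f.n_responses < rules.min_responses:
            reasons.append("too_few_responses")
        if rules.straddle_peak:
            pt = rules.session_peak_time
            if not (f.start < pt):
                reasons.append("start_not_before_peak")
            if not (f.stop > pt):
                reasons.append("stop_not_after_peak")
        if rules.early_response_cutoff is not None:
            if f.first_response is None or not (
                f.first_response < rules.early_response_cutoff
            ):
                reasons.append("early_response_cutoff")
        f.valid = not reasons
        f.exclusion_reasons = reasons
        out.append(f)
    return out


def summarize_start_stop(
    fits: Iterable[SingleTrialFit],
    group_fields: tuple[str, ...] = ("subject_id", "cue_id", "phase"),
) -> pd.DataFrame:
    """Mean start/stop over *valid* fits per subject × cue × phase.

    Groups with no valid fits are simply absent from the output (missing,
    never zero) — mirroring reduced degrees of freedom in downstream tests.
    """
    rows = []
    for f in fits:
        if not f.valid:
            continue
        subject_id, phase, session, trial_index = f.key
        rows.append(
            {
                "subject_id": subject_id,
                "cue_id": f.cue_id,
                "phase": phase,
                "start": f.start,
                "stop": f.stop,
            }
        )
    if not rows:
        return pd.DataFrame(columns=[*group_fields, "start", "stop", "n"])
    df = pd.DataFrame(rows)
    agg = df.groupby(list(group_fields), as_index=False).agg(
        start=("start", "mean"), stop=("stop", "mean"), n=("start", "size")
    )
    return agg


def fits_to_frame(fits: Iterable[SingleTrialFit]) -> pd.DataFrame:
    """Tidy table for ``singletrials.csv``."""
    rows = []
    for f in fits:
        subject_id, phase, session, trial_index = f.key
        rows.append(
            {
                "subject_id": subject_id,
                "phase": phase,
                "session": session,
                "trial_index": trial_index,
                "cue_id": f.cue_id,
                "start_s": f.start,
                "stop_s": f.stop,
                "r1": f.r1,
                "r2": f.r2,
                "r3": f.r3,
                "index": f.index,
                "n_responses": f.n_responses,
                "valid": f.valid,
                "exclusion_reasons": ";".join(f.exclusion_reasons),
            }
        )
    return pd.DataFrame(rows)
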