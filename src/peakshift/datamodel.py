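"""Trial-level data model for peak-interval experiments.

A peak-interval (PI) dataset is a flat collection of trials.  Each trial
carries the cue that was presented, the fixed interval (FI) programmed for
that cue, whether the trial was a rewarded FI trial or an unrewarded probe,
and the ordered nosepoke timestamps measured from cue onset.  Two linked
CSV tables (``trials.csv`` + ``responses.csv``) are the on-disk form; see
:mod:`peakshift.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

PHASES = ("train", "change", "test")
TRIAL_TYPES = ("fi", "probe")

#: Composite key uniquely identifying a trial within a dataset.
TrialKey = tuple[str, str, int, int]  # (subject_id, phase, session, trial_index)


class SchemaError(ValueError):
    """A CSV table is missing required columns or has malformed values."""


class IntegrityError(ValueError):
    """Linked tables disagree (orphan responses, duplicate trial keys)."""


class ValidationError(ValueError):
    """A trial violates a structural invariant (e.g. non-monotone times)."""


@dataclass
class TrialRecord:
    """One trial: metadata plus ordered response timestamps (s from cue onset).

    ``probe_duration`` is set for probe trials only; ``reinforced_time`` (the
    rewarded response that terminated the trial) for FI trials only.
    """

    subject_id: str
    group: str
    context: str
    phase: str
    session: int
    trial_index: int
    cue_id: str
    trial_type: str
    programmed_duration: float
    probe_duration: Optional[float] = None
    reinforced_time: Optional[float] = None
    responses: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)

    @property
    def key(self) -> TrialKey:
        return (self.subject_id, self.phase, self.session, self.trial_index)

    @property
    def trial_end(self) -> float:
        """Trial duration: probe length for probes, rewarded time for FI."""
        if self.trial_type == "probe":
            return float(self.probe_duration)
        return float(self.reinforced_time)

    @property
    def n_responses(self) -> int:
        return int(self.responses.size)

    @property
    def first_response(self) -> Optional[float]:
        return float(self.responses[0]) if self.responses.size else None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialRecord):
            return NotImplemented
        scalar = all(
            getattr(self, f) == getattr(other, f)
            for f in (
                "subject_id", "group", "context", "phase", "session",
                "trial_index", "cue_id", "trial_type",
            )
        )
        near = (
            _close(self.programmed_duration, other.programmed_duration)
            and _close(self.probe_duration, other.probe_duration)
            and _close(self.reinforced_time, other.reinforced_time)
        )
        resp = self.responses.size == other.responses.size and np.allclose(
            self.responses, other.responses, rtol=0.0, atol=1e-6
        )
        return scalar and near and resp


def _close(a: Optional[float], b: Optional[float], atol: float = 1e-6) -> bool:
    if a is None or b is None:
        return (a is None) == (b is None)
    return abs(float(a) - float(b)) <= atol


@dataclass
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    key: TrialKey
    rule: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.key}: {self.rule} — {self.detail}"


@dataclass
class Dataset:
    """A collection of :class:`TrialRecord` with a design label and provenance."""

    trials: list[TrialRecord]
    design_label: str = ""
    provenance: str = ""

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.design_label == other.design_label
            and len(self.trials) == len(other.trials)
            and all(a == b for a, b in zip(self.trials, other.trials))
        )

    def select(
        self,
        subject_id: Optional[str] = None,
        cue_id: Optional[str] = None,
        phase: Optional[str] = None,
        context: Optional[str] = None,
        trial_type: Optional[str] = None,
        group: Optional[str] = None,
    ) -> list[TrialRecord]:
        """Filter trials by any combination of key fields."""
        out = []
        for t in self.trials:
            if subject_id is not None and t.subject_id != subject_id:
                continue
            if cue_id is not None and t.cue_id != cue_id:
                continue
            if phase is not None and t.phase != phase:
                continue
            if context is not None and t.context != context:
                continue
            if trial_type is not None and t.trial_type != trial_type:
                continue
            if group is not None and t.group != group:
                continue
            out.append(t)
        return out

    @property
    def subjects(self) -> list[str]:
        return sorted({t.subject_id for t in self.trials})

    def cues(self, phase: Optional[str] = None) -> list[str]:
        return sorted({t.cue_id for t in self.trials if phase is None or t.phase == phase})

    def sessions(self, phase: str) -> list[int]:
        return sorted({t.session for t in self.trials if t.phase == phase})

    def contexts(self, phase: Optional[str] = None) -> list[str]:
        return sorted({t.context for t in self.trials if phase is None or t.phase == phase})


@dataclass
class AnalysisConfig:
    """Knobs shared by the binning / single-trial / shift stages.

    ``sessions_per_phase`` matches the number of final training sessions used
    for the training average to the number of test sessions; ``None`` infers
    it from the data (count of distinct test sessions).
    ``early_response_cutoff`` excludes probe trials whose first response does
    not occur before the cutoff (used for the 8-to-4 design, cutoff 32 s).
    """

    bin_width: float = 1.0
    sessions_per_phase: Optional[int] = None
    early_response_cutoff: Optional[float] = None
    min_responses: int = 3
    straddle_peak: bool = True

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.sessions_per_phase is not None and self.sessions_per_phase < 1:
            raise ValueError("sessions_per_phase must be >= 1")


def validate_trial(trial: TrialRecord) -> list[Violation]:
    """Check a single trial against the structural invariants."""
    v: list[Violation] = []
    key = trial.key

    if trial.phase not in PHASES:
        v.append(Violation(key, "phase_enum", f"unknown phase {trial.phase!r}"))
    if trial.trial_type not in TRIAL_TYPES:
        v.append(Violation(key, "trial_type_enum", f"unknown type {trial.trial_type!r}"))
        return v
    if trial.programmed_duration is None or trial.programmed_duration <= 0:
        v.append(Violation(key, "programmed_duration_positive",
                           f"got {trial.programmed_duration}"))

    if trial.trial_type == "probe":
        if trial.probe_duration is None:
            v.append(Violation(key, "probe_duration_missing", "probe trial lacks probe_duration"))
        if trial.reinforced_time is not None:
            v.append(Violation(key, "probe_has_reinforced_time",
                               "probe trials are never rewarded"))
    else:  # fi
        if trial.reinforced_time is None:
            v.append(Violation(key, "reinforced_time_missing", "fi trial lacks reinforced_time"))
        elif trial.programmed_duration is not None and (
            trial.reinforced_time < trial.programmed_duration - 1e-9
        ):
            v.append(Violation(key, "reinforced_before_criterion",
                               f"reinforced at {trial.reinforced_time} < FI "
                               f"{trial.programmed_duration}"))
        if trial.probe_duration is not None:
            v.append(Violation(key, "fi_has_probe_duration", "fi trial carries probe_duration"))

    r = trial.responses
    if r.size:
        if np.any(np.diff(r) < 0):
            v.append(Violation(key, "responses_monotone", "timestamps decrease"))
        if r[0] < 0:
            v.append(Violation(key, "response_before_onset", f"t={r[0]}"))
        end = None
        try:
            end = trial.trial_end
        except (TypeError, ValueError):
            pass
        if end is not None and r[-1] > end + 1e-9:
            v.append(Violation(key, "response_after_trial_end",
                               f"t={r[-1]} > end={end}"))
        if (
            trial.trial_type == "fi"
            and trial.reinforced_time is not None
            and trial.programmed_duration is not None
        ):
            # A rewarded response terminates the trial, so the open interval
            # (FI, reinforced_time) must contain no responses.
            inside = (r > trial.programmed_duration + 1e-9) & (
                r < trial.reinforced_time - 1e-9
            )
            if np.any(inside):
                v.append(Violation(key, "response_between_fi_and_reward",
                                   f"{int(inside.sum())} responses in open interval"))
    return v


def validate_dataset(dataset: Dataset) -> list[Violation]:
    """Validate every trial plus cross-trial invariants.

    Violations are returned as data, never raised: an empty list means the
    dataset satisfies all invariants.
    """
    out: list[Violation] = []
    seen: set[TrialKey] = set()
    for t in dataset:
        if t.key in seen:
            out.append(Violation(t.key, "duplicate_key", "trial key repeated"))
        seen.add(t.key)
        out.extend(validate_trial(t))

    # every test cue must have been introduced earlier (training, or the
    # change phase for designs that add a novel cue there)
    earlier_cues = {t.cue_id for t in dataset if t.phase in ("train", "change")}
    test_cues = {t.cue_id for t in dataset if t.phase == "test"}
    for cue in sorted(test_cues - earlier_cues):
        any_key = next(t.key for t in dataset if t.phase == "test" and t.cue_id == cue)
        out.append(Violation(any_key, "test_cue_untrained",
                             f"cue {cue!r} appears in test but never before"))
    return out
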