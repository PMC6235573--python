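"""Phase plans for the five cross-cue transfer designs.

Every experiment runs train → change → test.  During training two or three
cues each predict reward after a distinct fixed interval, with 30% of each
cue's trials presented as long unrewarded probes.  During the change phase
one cue is withheld and the remaining cue(s) are retrained (with the same or
a new duration).  At test the withheld cue returns as probe-only trials (20%
of trials) while the retrained cues continue as in the change phase.

Probe trials last 3–4× the longest duration in effect for the phase, unless
a design pins an explicit probe range (the 32-s designs use 96–128 s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

TRAIN_PROBE_FRACTION = 0.30   # probes among each cue's trials in train/change
TEST_PROBE_FRACTION = 0.20    # probes for the reintroduced cue at test
PROBE_FACTOR_RANGE = (3.0, 4.0)


@dataclass
class CueSpec:
    """One cue's role within a phase.

    ``duration`` is the programmed FI criterion in seconds (for probe-only
    cues it is the duration expectation used only to size probe lengths).
    """

    duration: float
    probe_fraction: float = TRAIN_PROBE_FRACTION
    probe_only: bool = False
    weight: float = 1.0  # relative presentation probability

    def __post_init__(self) -> None:
        if not (0.0 <= self.probe_fraction <= 1.0):
            raise ValueError("probe_fraction must lie in [0, 1]")
        if self.duration <= 0:
            raise ValueError("cue duration must be positive")


@dataclass
class PhaseSpec:
    name: str                      # train | change | test
    cues: dict[str, CueSpec]
    context: str = "A"
    sessions: int = 2
    trials_per_session: int = 120
    probe_range: Optional[tuple[float, float]] = None  # explicit probe bounds

    def probe_bounds(self) -> tuple[float, float]:
        """Probe-length bounds: pinned range, else 3–4× the longest duration."""
        if self.probe_range is not None:
            return self.probe_range
        longest = max(c.duration for c in self.cues.values())
        return (PROBE_FACTOR_RANGE[0] * longest, PROBE_FACTOR_RANGE[1] * longest)


@dataclass
class PhasePlan:
    """Complete phase/cue/duration structure for one design."""

    design: str
    phases: list[PhaseSpec]
    covariance_violated: bool = False  # uncorrelated designs: transfer blocked

    def phase(self, name: str) -> PhaseSpec:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(f"plan {self.design!r} has no phase {name!r}")

    @property
    def change_context(self) -> str:
        return self.phase("change").context

    def train_duration(self, cue_id: str) -> float:
        return self.phase("train").cues[cue_id].duration

    def retrained_cues(self) -> dict[str, float]:
        """Cues presented (reinforced) during the change phase → duration."""
        return {
            c: spec.duration
            for c, spec in self.phase("change").cues.items()
            if not spec.probe_only
        }

    def withheld_cues(self) -> list[str]:
        """Trained cues omitted during the change phase."""
        change = set(self.phase("change").cues)
        return sorted(set(self.phase("train").cues) - change)

    def changed_cue_shift(self) -> float:
        """Mean proportional duration shift Δ over explicitly retrained cues.

        Δ = (new − old)/old averaged over cues present in both train and
        change; 0.0 when no retrained cue actually changed duration.
        """
        train = self.phase("train").cues
        deltas = [
            (d1 - train[c].duration) / train[c].duration
            for c, d1 in self.retrained_cues().items()
            if c in train
        ]
        changed = [d for d in deltas if abs(d) > 1e-12]
        if not changed:
            return 0.0
        return sum(changed) / len(changed)


DESIGN_NAMES = (
    "exp1_8to4", "exp1_16to32", "exp1_control", "exp2_8to12",
    "exp3_change", "exp3_nochange",
    "exp4a_correlated", "exp4a_uncorrelated",
    "exp4b_correlated", "exp4b_uncorrelated",
    "exp5_context",
)


def _two_cue_plan(
    design: str,
    train: dict[str, float],
    change: dict[str, float],
    test_fi: dict[str, float],
    test_probe_only: dict[str, float],
    probe_range_by_phase: Optional[dict[str, tuple[float, float]]] = None,
) -> PhasePlan:
    pr = probe_range_by_phase or {}
    phases = [
        PhaseSpec("train", {c: CueSpec(d) for c, d in train.items()},
                  probe_range=pr.get("train")),
        PhaseSpec("change", {c: CueSpec(d) for c, d in change.items()},
                  probe_range=pr.get("change")),
        PhaseSpec(
            "test",
            {
                **{c: CueSpec(d) for c, d in test_fi.items()},
                **{
                    c: CueSpec(d, probe_fraction=1.0, probe_only=True,
                               weight=TEST_PROBE_FRACTION / (1 - TEST_PROBE_FRACTION)
                               * len(test_fi) if test_fi else 1.0)
                    for c, d in test_probe_only.items()
                },
            },
            probe_range=pr.get("test"),
        ),
    ]
    return PhasePlan(design, phases)


def plan_experiment(design_name: str, **overrides) -> PhasePlan:
    """Return the preset :class:`PhasePlan` for a named design.

    Keyword overrides patch phase attributes uniformly:
    ``sessions_train`` / ``sessions_change`` / ``sessions_test`` and
    ``trials_per_session_<phase>`` (or ``trials_per_session`` for all).
    """
    if design_name not in DESIGN_NAMES:
        raise ValueError(f"unknown design {design_name!r}; expected one of {DESIGN_NAMES}")

    big = (96.0, 128.0)
    if design_name == "exp1_8to4":
        plan = _two_cue_plan(design_name, {"short": 8, "long": 16},
                             {"short": 4}, {"short": 4}, {"long": 16})
    elif design_name == "exp1_16to32":
        plan = _two_cue_plan(design_name, {"short": 8, "long": 16},
                             {"long": 32}, {"long": 32}, {"short": 8},
                             {"change": big, "test": big})
    elif design_name == "exp1_control":
        plan = _two_cue_plan(design_name, {"short": 8, "long": 16},
                             {"short": 8}, {"short": 8}, {"long": 16})
    elif design_name == "exp2_8to12":
        plan = _two_cue_plan(design_name, {"short": 8, "long": 16},
                             {"short": 12}, {"short": 12}, {"long": 16})
    elif design_name == "exp3_change":
        plan = _two_cue_plan(design_name, {"short": 8, "long": 16},
                             {"short": 4, "novel": 8},
                             {"short": 4, "novel": 8}, {"long": 16})
    elif design_name == "exp3_nochange":
        plan = _two_cue_plan(design_name, {"short": 8, "long": 16},
                             {"short": 8, "novel": 4},
                             {"short": 8, "novel": 4}, {"long": 16})
    elif design_name in ("exp4a_correlated", "exp4b_correlated"):
        pr = {"train": big, "change": big, "test": big} if "4a" in design_name else \
             {"change": big, "test": big}
        plan = _two_cue_plan(design_name, {"short": 4, "medium": 8, "long": 16},
                             {"short": 8, "long": 32},
                             {"short": 8, "long": 32}, {"medium": 8}, pr)
    elif design_name in ("exp4a_uncorrelated", "exp4b_uncorrelated"):
        pr = {"train": big, "change": big, "test": big} if "4a" in design_name else \
             {"change": big, "test": big}
        plan = _two_cue_plan(design_name, {"short": 4, "medium": 8, "long": 16},
                             {"short": 4, "long": 32},
                             {"short": 4, "long": 32}, {"medium": 8}, pr)
        plan.covariance_violated = True
    else:  # exp5_context
        # Trained in context A, retrained (16→32) in context B; test is two
        # sessions, one per context, with both cues probe-only at equal rates.
        test_cues = {
            "short": CueSpec(8, probe_fraction=1.0, probe_only=True),
            "long": CueSpec(32, probe_fraction=1.0, probe_only=True),
        }
        plan = PhasePlan(
            design_name,
            [
                PhaseSpec("train", {"short": CueSpec(8), "long": CueSpec(16)},
                          context="A", probe_range=big),
                PhaseSpec("change", {"long": CueSpec(32)}, context="B",
                          probe_range=big),
                PhaseSpec("test", dict(test_cues), context="B", sessions=1,
                          probe_range=big),
                PhaseSpec("test", dict(test_cues), context="A", sessions=1,
                          probe_range=big),
            ],
        )

    return _apply_overrides(plan, overrides)


def _apply_overrides(plan: PhasePlan, overrides: dict) -> PhasePlan:
    for key, value in overrides.items():
        parts = key.rsplit("_", 1)
        if key in {"sessions", "trials_per_session"}:
            attr, targets = key, None
        elif parts[-1] in {"train", "change", "test"} and parts[0] in {
            "sessions", "trials_per_session"
        }:
            attr, targets = parts[0], parts[-1]
        else:
            raise ValueError(f"unknown plan override {key!r}")
        for p in plan.phases:
            if targets is None or p.name == targets:
                setattr(p, attr, int(value))
    return plan
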