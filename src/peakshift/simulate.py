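"""Generative model of peak-interval behavior.

Single trials follow the break-run-break account: responding sits at a low
baseline rate, switches abruptly to a high rate in a "run" bracketing the
expected reward time, then falls back.  The run midpoint is drawn around the
subject's effective peak time with scalar (CV-constant) noise, and the run
half-width scales with the peak time, which is what makes simulated peak
functions obey the scalar property of interval timing.

Cross-cue transfer is a proportional rule: when a retrained cue's duration
shifts by a fraction Δ, a withheld cue's effective peak time at test becomes
``D0 · (1 + τ_eff · Δ)``, where τ_eff is the transfer coefficient ``tau``,
multiplied by ``context_attenuation`` when testing in a context where the
change was never experienced, and forced to 0 in covariance-violated
(uncorrelated) designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import Dataset, TrialRecord
from .designs import PhasePlan, PhaseSpec, plan_experiment

_MAX_FI_RETRIES = 50


@dataclass
class SimConfig:
    """Generator parameters (rates in responses/s, CVs dimensionless).

    Defaults are repository calibrations, documented in the methods note:
    ``tau`` = 0.5 and ``context_attenuation`` = 0.4 approximate the observed
    transfer pattern (≈½ of the changed cue's proportional shift, roughly
    0.4× further attenuation outside the change context).
    """

    plan: PhasePlan
    n_subjects: int = 10
    r_low: float = 0.05
    r_high: float = 1.5
    gamma: float = 0.15          # scalar CV of the run midpoint
    omega: float = 0.35          # run half-width as a fraction of peak time
    eta: float = 0.10            # CV of the half-width
    tau: float = 0.5             # transfer coefficient
    context_attenuation: float = 0.4
    subject_bias_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_low < 0 or self.r_high <= self.r_low:
            raise ValueError("need 0 <= r_low < r_high")
        if self.gamma < 0 or self.eta < 0 or self.subject_bias_cv < 0:
            raise ValueError("CV parameters must be >= 0")
        if not (0.0 < self.omega < 1.0):
            raise ValueError("omega must lie in (0, 1)")
        if not (0.0 <= self.context_attenuation <= 1.0):
            raise ValueError("context_attenuation must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass
class SubjectState:
    """Per-subject timing bias and private RNG stream."""

    subject_id: str
    bias: dict[str, float]                 # cue_id -> multiplicative bias
    rng: np.random.Generator

    def cue_bias(self, cue_id: str) -> float:
        return self.bias.get(cue_id, 1.0)


def make_subjects(config: SimConfig) -> list[SubjectState]:
    """Spawn independent, reproducible per-subject RNG streams and biases.

    The bias is drawn once per subject × cue and held fixed across phases,
    so within-subject percent changes are bias-free.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects)
    cues = sorted({c for p in config.plan.phases for c in p.cues})
    subjects = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        bias = {
            c: max(0.1, 1.0 + config.subject_bias_cv * rng.standard_normal())
            for c in cues
        }
        subjects.append(SubjectState(f"s{i + 1:02d}", bias, rng))
    return subjects


def effective_peak_time(
    cue_id: str,
    phase: str,
    context: str,
    plan: PhasePlan,
    config: SimConfig,
    subject: Optional[SubjectState] = None,
) -> float:
    """Expected time of reward for a cue in a given phase and context.

    Train/change phases express the programmed durations directly.  At test,
    explicitly retrained cues keep their (possibly new) duration, while cues
    withheld during the change phase inherit a fraction ``τ_eff`` of the
    changed cue's proportional shift.
    """
    bias = subject.cue_bias(cue_id) if subject is not None else 1.0
    train_cues = plan.phase("train").cues

    if phase == "train":
        if cue_id not in train_cues:
            raise KeyError(f"cue {cue_id!r} not in training phase")
        return train_cues[cue_id].duration * bias
    if phase == "change":
        change_cues = plan.phase("change").cues
        if cue_id not in change_cues:
            raise KeyError(f"cue {cue_id!r} not presented during change phase")
        return change_cues[cue_id].duration * bias

    # test phase
    retrained = plan.retrained_cues()
    if cue_id in retrained:
        return retrained[cue_id] * bias
    if cue_id not in train_cues:
        raise KeyError(f"cue {cue_id!r} unknown to plan {plan.design!r}")

    d0 = train_cues[cue_id].duration
    delta = plan.changed_cue_shift()
    if plan.covariance_violated:
        tau_eff = 0.0
    elif context != plan.change_context:
        tau_eff = config.tau * config.context_attenuation
    else:
        tau_eff = config.tau
    return d0 * (1.0 + tau_eff * delta) * bias


def sample_run_window(
    pt_eff: float, config: SimConfig, rng: np.random.Generator, size: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Draw run midpoints and half-widths for ``size`` trials.

    m ~ Normal(pt_eff, gamma·pt_eff); h ~ Normal(omega·pt_eff,
    eta·omega·pt_eff) truncated to h > 0 by redraw.
    """
    if not np.isfinite(pt_eff) or pt_eff <= 0:
        raise ValueError("pt_eff must be finite and positive")
    m = rng.normal(pt_eff, config.gamma * pt_eff, size=size)
    h_mu = config.omega * pt_eff
    h = rng.normal(h_mu, config.eta * h_mu, size=size)
    for _ in range(100):
        bad = h <= 0
        if not bad.any():
            break
        h[bad] = rng.normal(h_mu, config.eta * h_mu, size=int(bad.sum()))
    h = np.maximum(h, 1e-9)
    return m, h


def _poisson_segment(rate: float, a: float, b: float, rng: np.random.Generator) -> np.ndarray:
    if b <= a or rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * (b - a))
    if n == 0:
        return np.empty(0)
    return np.sort(rng.uniform(a, b, size=n))


def sample_trial(
    pt_eff: float,
    trial_type: str,
    probe_duration: Optional[float],
    programmed_duration: float,
    config: SimConfig,
    rng: np.random.Generator,
    meta: Optional[dict] = None,
) -> TrialRecord:
    """Sample one break-run-break trial as a :class:`TrialRecord`.

    Probe trials run for ``probe_duration`` regardless of responding.  FI
    trials end at the first response at or after ``programmed_duration``
    (the rewarded response); when ``r_low`` is 0 and the run ends before the
    criterion, the trial is resampled up to a bounded retry count, after
    which a single response at the criterion is injected.
    """
    meta = meta or {}
    if trial_type == "probe":
        if probe_duration is None or probe_duration <= pt_eff:
            raise ValueError("probe_duration must exceed pt_eff for probe trials")
        T = float(probe_duration)
        m, h = sample_run_window(pt_eff, config, rng)
        a = float(np.clip(m[0] - h[0], 0.0, T))
        b = float(np.clip(m[0] + h[0], 0.0, T))
        resp = np.concatenate(
            [
                _poisson_segment(config.r_low, 0.0, a, rng),
                _poisson_segment(config.r_high, a, b, rng),
                _poisson_segment(config.r_low, b, T, rng),
            ]
        )
        return TrialRecord(
            trial_type="probe",
            programmed_duration=programmed_duration,
            probe_duration=T,
            reinforced_time=None,
            responses=resp,
            **meta,
        )

    if trial_type != "fi":
        raise ValueError(f"unknown trial_type {trial_type!r}")

    D = float(programmed_duration)
    for _ in range(_MAX_FI_RETRIES):
        m, h = sample_run_window(pt_eff, config, rng)
        a = float(max(m[0] - h[0], 0.0))
        b = float(max(m[0] + h[0], a))
        horizon = max(b, D)
        resp = np.concatenate(
            [
                _poisson_segment(config.r_low, 0.0, min(a, horizon), rng),
                _poisson_segment(config.r_high, min(a, horizon), min(b, horizon), rng),
                _poisson_segment(config.r_low, b, horizon, rng) if D > b else np.empty(0),
            ]
        )
        resp.sort()
        after = resp[resp >= D]
        if after.size:
            rt = float(after[0])
            resp = resp[resp <= rt]
            break
        if config.r_low > 0:
            # Memoryless low-rate process beyond the horizon: first arrival
            # at or after max(b, D) is horizon + Exp(r_low).
            rt = horizon + float(rng.exponential(1.0 / config.r_low))
            resp = np.append(resp, rt)
            break
    else:
        rt = D
        resp = np.append(resp[resp < D], D)  # injected rewarded response

    return TrialRecord(
        trial_type="fi",
        programmed_duration=D,
        probe_duration=None,
        reinforced_time=rt,
        responses=resp,
        **meta,
    )


def simulate(config: SimConfig) -> Dataset:
    """Run the full plan for all subjects; deterministic given ``config.seed``.

    Within a session the cue of each trial is drawn by presentation weight
    and probe status by a per-trial Bernoulli draw at the cue's probe
    fraction; probe lengths are uniform on the phase's probe bounds.
    """
    plan = config.plan
    subjects = make_subjects(config)
    trials: list[TrialRecord] = []

    for subj in subjects:
        for phase in plan.phases:
            cue_ids = sorted(phase.cues)
            weights = np.array([phase.cues[c].weight for c in cue_ids], float)
            weights /= weights.sum()
            lo, hi = phase.probe_bounds()
            session_offset = _session_offset(plan, phase)
            for sess in range(1, phase.sessions + 1):
                for idx in range(1, phase.trials_per_session + 1):
                    cue = cue_ids[subj.rng.choice(len(cue_ids), p=weights)]
                    spec = phase.cues[cue]
                    is_probe = spec.probe_only or (
                        subj.rng.random() < spec.probe_fraction
                    )
                    pt = effective_peak_time(
                        cue, phase.name, phase.context, plan, config, subj
                    )
                    meta = dict(
                        subject_id=subj.subject_id,
                        group=plan.design,
                        context=phase.context,
                        phase=phase.name,
                        session=session_offset + sess,
                        trial_index=idx,
                        cue_id=cue,
                    )
                    if is_probe:
                        probe_len = float(subj.rng.uniform(lo, hi))
                        probe_len = max(probe_len, pt * 1.5)  # guard huge biases
                        trials.append(
                            sample_trial(pt, "probe", probe_len, spec.duration,
                                         config, subj.rng, meta)
                        )
                    else:
                        trials.append(
                            sample_trial(pt, "fi", None, spec.duration,
                                         config, subj.rng, meta)
                        )

    return Dataset(
        trials=trials,
        design_label=plan.design,
        provenance=f"simulate:{plan.design}:seed={config.seed}",
    )


def _session_offset(plan: PhasePlan, phase: PhaseSpec) -> int:
    """Sessions are numbered consecutively across repeated phase entries
    (exp5's two test sessions, one per context, get distinct numbers)."""
    offset = 0
    for p in plan.phases:
        if p is phase:
            return offset
        if p.name == phase.name:
            offset += p.sessions
    return offset


def simulate_design(design_name: str, seed: int = 0, n_subjects: int = 10,
                    **kwargs) -> Dataset:
    """Convenience: plan + simulate in one call.

    Plan overrides (``sessions_train`` etc.) may be passed through ``kwargs``
    alongside :class:`SimConfig` fields.
    """
    plan_keys = {
        k: kwargs.pop(k)
        for k in list(kwargs)
        if k.startswith(("sessions", "trials_per_session"))
    }
    plan = plan_experiment(design_name, **plan_keys)
    return simulate(SimConfig(plan=plan, seed=seed, n_subjects=n_subjects, **kwargs))
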