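"""Self-contained reproduction runs at the package's study conditions.

Each function regenerates its inputs with the simulator, runs the full
analysis path, and returns plain numbers.  Problem sizes follow the study
conditions the package is calibrated to: groups of 10 (or 5 for the
three-cue designs) subjects and roughly 40 probe trials per analysis cell,
with training sessions matched in number to test sessions.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import (
    AnalysisConfig,
    cue_shift_summary,
    fit_low_high_low,
    fit_peak,
    gg_model,
    no_shift_evidence,
    peak_fit_table,
    plan_experiment,
    simulate_design,
)
from .peaks import PeakFunction
from .simulate import SimConfig, sample_run_window, sample_trial
from .single_trial import lhl_objective

_MOD = 2**31 - 1


def _derive_seed(base: int, stream: int, index: int = 0) -> int:
    """Deterministic sub-seed below 2**31 for independent runs."""
    return (base * 1_000_003 + stream * 7_919 + index) % _MOD


# ---------------------------------------------------------------------------
# model identities and noiseless recovery

def gg_k2_gaussian_supnorm() -> float:
    """Sup-norm between the K = 2 model and the ordinary Gaussian closed
    form over t in [0, 128] at 0.01-s resolution."""
    t = np.arange(0.0, 128.0 + 1e-9, 0.01)
    b, s, pt, sp = 0.1, 1.0, 40.0, 8.0
    gauss = b + s * np.exp(-((t - pt) ** 2) / (2 * sp**2))
    return float(np.max(np.abs(gg_model(t, b, s, pt, sp, 2.0) - gauss)))


def noiseless_recovery_max_rel_error(
    pts=(8.0, 16.0, 32.0),
    sps_rel=(0.15, 0.25, 0.40),
    ks=(1.5, 2.0, 3.0),
) -> float:
    """Worst relative parameter-recovery error over a 3x3x3 generator grid
    of (PT, SP, K), fitting noiseless peak functions."""
    worst = 0.0
    for pt in pts:
        for sp_rel in sps_rel:
            for k in ks:
                sp = sp_rel * pt
                t_end = int(4 * pt)
                edges = np.arange(t_end + 1, dtype=float)
                centers = 0.5 * (edges[:-1] + edges[1:])
                rate = gg_model(centers, 0.1, 1.0, pt, sp, k)
                pf = PeakFunction("s", "c", "train", "A", edges, rate, 1)
                fit = fit_peak(pf)
                for got, true in [(fit.B, 0.1), (fit.S, 1.0), (fit.PT, pt),
                                  (fit.SP, sp), (fit.K, k)]:
                    worst = max(worst, abs(got - true) / abs(true))
    return float(worst)


# ---------------------------------------------------------------------------
# full-pipeline transfer runs

_EXP1_SCALE = dict(
    sessions_train=2, trials_per_session_train=135,
    sessions_change=1, trials_per_session_change=20,
    sessions_test=2, trials_per_session_test=100,
)
_EXP4_SCALE = dict(
    sessions_train=2, trials_per_session_train=200,
    sessions_change=1, trials_per_session_change=20,
    sessions_test=2, trials_per_session_test=100,
)


def exp1_16to32_shifts(seed: int, n_seeds: int = 20, tau: float = 0.59) -> dict:
    """Unchanged- and changed-cue percent shifts for the 16-to-32 design.

    Simulates n = 10 subjects per seed (about 40 probe trials per cell),
    fits peak functions for training and test, and averages the per-seed
    group mean percent changes over ``n_seeds`` independent runs.
    """
    unchanged, changed = [], []
    for i in range(n_seeds):
        ds = simulate_design(
            "exp1_16to32", seed=_derive_seed(seed, 1, i),
            n_subjects=10, tau=tau, **_EXP1_SCALE,
        )
        fits = peak_fit_table(ds)
        unchanged.append(cue_shift_summary(fits, "short").mean)
        changed.append(cue_shift_summary(fits, "long").mean)
    return {
        "unchanged_cue_shift_pct": float(np.mean(unchanged)),
        "changed_cue_shift_pct": float(np.mean(changed)),
        "n_seeds": n_seeds,
        "n_subjects": 10,
    }


def exp4_uncorrelated_block(seed: int, n_replicates: int = 100) -> dict:
    """Covariance-violation check: middle-cue shifts and no-shift evidence.

    Each replicate simulates the uncorrelated (transfer-blocked) and
    correlated (reference) groups with n = 5 subjects each, computes the
    middle-cue percent shifts, and evaluates the incremental-prior Bayes
    factor for "no shift" in the uncorrelated group.
    """
    shifts, bf_hits = [], 0
    for i in range(n_replicates):
        unc = simulate_design(
            "exp4a_uncorrelated", seed=_derive_seed(seed, 2, i),
            n_subjects=5, **_EXP4_SCALE,
        )
        cor = simulate_design(
            "exp4a_correlated", seed=_derive_seed(seed, 3, i),
            n_subjects=5, **_EXP4_SCALE,
        )
        u = cue_shift_summary(peak_fit_table(unc, cues=["medium"]), "medium")
        c = cue_shift_summary(peak_fit_table(cor, cues=["medium"]), "medium")
        shifts.append(u.mean)
        bf = no_shift_evidence(u.pct_changes, c.pct_changes, prior="incremental")
        bf_hits += bf.bf > 1.0
    return {
        "middle_cue_shift_pct": float(np.mean(shifts)),
        "bf_gt1_fraction": bf_hits / n_replicates,
        "n_replicates": n_replicates,
        "n_subjects_per_group": 5,
    }


# ---------------------------------------------------------------------------
# single-trial oracle

def _brute_force_low_high_low(times: np.ndarray, T: float):
    """Independent naive double loop over all candidate change-point pairs."""
    cand = np.unique(times)
    best_val, best_s, best_e = -np.inf, None, None
    for s in cand:
        for e in cand:
            if e < s:
                continue
            val = lhl_objective(times, T, s, e)
            if val > best_val + 1e-12:
                best_val, best_s, best_e = val, s, e
    return best_val, best_s, best_e


def single_trial_oracle_agreement(seed: int, n_trials: int = 1000) -> dict:
    """Fraction of random simulated probe trials on which the exhaustive
    fit agrees exactly with the brute-force oracle (should be 1.0)."""
    plan = plan_experiment("exp1_8to4")
    cfg = SimConfig(plan=plan, seed=0)
    rng = np.random.default_rng(_derive_seed(seed, 4))
    agree = 0
    done = 0
    while done < n_trials:
        pt = float(rng.choice([8.0, 16.0]))
        probe = float(rng.uniform(3 * pt, 4 * pt))
        t = sample_trial(pt, "probe", probe, pt, cfg, rng, meta=dict(
            subject_id="s01", group="g", context="A", phase="train",
            session=1, trial_index=done + 1, cue_id="c"))
        if t.n_responses < 2:
            continue
        done += 1
        fit = fit_low_high_low(t)
        val, s, e = _brute_force_low_high_low(t.responses, t.trial_end)
        if (abs(fit.index - val) < 1e-9 and fit.start == s and fit.stop == e):
            agree += 1
    return {"agreement_fraction": agree / n_trials, "n_trials": n_trials}


def single_trial_hand_example() -> dict:
    """The enumerable fixture: responses {10, 11, 12} in a 48-s probe."""
    from .datamodel import TrialRecord

    t = TrialRecord("s01", "g", "A", "train", 1, 1, "c", "probe", 8.0, 48.0,
                    None, np.array([10.0, 11.0, 12.0]))
    fit = fit_low_high_low(t)
    return {"start": fit.start, "stop": fit.stop, "index": fit.index}


# ---------------------------------------------------------------------------
# Bayes oracles

def conjugate_bf_max_rel_error(n_points: int = 50) -> float:
    """Max relative disagreement between the grid BF and the normal-normal
    closed form over a deterministic parameter sweep."""
    from .bayes import Prior, ThetaGrid, marginal_likelihood

    worst = 0.0
    rng = np.random.default_rng(12345)  # fixed: part of the sweep definition
    grid = ThetaGrid.span(-150.0, 150.0, 0.05)
    for i in range(n_points):
        n = int(rng.integers(4, 12))
        sd = float(rng.uniform(3, 10))
        values = rng.normal(rng.uniform(-10, 10), sd, size=n)
        mu0, tau0 = float(rng.uniform(-5, 5)), float(rng.uniform(2, 8))
        mu1, tau1 = float(rng.uniform(-20, 20)), float(rng.uniform(2, 8))
        like = marginal_likelihood(values, sd, grid)
        p0 = stats.norm.pdf(grid.theta, mu0, tau0)
        p1 = stats.norm.pdf(grid.theta, mu1, tau1)
        from .bayes import bayes_factor

        res = bayes_factor(
            like,
            Prior(grid, p0 / (p0.sum() * grid.step), "null"),
            Prior(grid, p1 / (p1.sum() * grid.step), "reference"),
        )
        s_n2 = sd**2 / n
        closed = (
            stats.norm.pdf(values.mean(), mu0, np.sqrt(s_n2 + tau0**2))
            / stats.norm.pdf(values.mean(), mu1, np.sqrt(s_n2 + tau1**2))
        )
        worst = max(worst, abs(res.bf - closed) / closed)
    return float(worst)


def bf_grid_refinement_rel_change(step_coarse: float = 0.05,
                                  step_fine: float = 0.005) -> float:
    """Relative BF change when the grid is refined 10x."""
    data = [2.0, -1.0, 4.0, 0.5, -2.5]
    ref = [30.0, 42.0, 38.0, 35.0, 44.0]
    coarse = no_shift_evidence(data, ref, prior="incremental", step=step_coarse)
    fine = no_shift_evidence(data, ref, prior="incremental", step=step_fine)
    return float(abs(coarse.bf - fine.bf) / fine.bf)


# ---------------------------------------------------------------------------
# scalar property

def scalar_property_cvs(seed: int, n_per_level: int = 5000,
                        pts=(8.0, 16.0, 32.0)) -> dict:
    """CV of run midpoints per trained interval, with a Feltz-Miller
    equality-of-CVs test across the levels (p > 0.05 = no reliable change)."""
    plan = plan_experiment("exp1_8to4")
    cfg = SimConfig(plan=plan, seed=0)
    rng = np.random.default_rng(_derive_seed(seed, 5))
    cvs, ns = [], []
    for pt in pts:
        m, _ = sample_run_window(pt, cfg, rng, size=n_per_level)
        cvs.append(float(m.std(ddof=1) / m.mean()))
        ns.append(n_per_level)
    p = _feltz_miller_p(cvs, ns)
    return {
        "cv_by_level": dict(zip([str(int(p_)) for p_ in pts], cvs)),
        "cv_max_min_ratio": max(cvs) / min(cvs),
        "feltz_miller_p": p,
        "n_per_level": n_per_level,
    }


def _feltz_miller_p(cvs, ns) -> float:
    """Asymptotic k-sample test for equality of coefficients of variation."""
    cvs = np.asarray(cvs, float)
    u = np.asarray(ns, float) - 1.0
    cv_pool = float(np.sum(u * cvs) / np.sum(u))
    d = np.sum(u * (cvs - cv_pool) ** 2) / (cv_pool**2 * (0.5 + cv_pool**2))
    return float(stats.chi2.sf(d, len(cvs) - 1))
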