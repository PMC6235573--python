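"""End-to-end helpers: dataset → fits table → shift table → evidence.

These functions are the glue used by the CLI and by reproduction scripts;
each stage delegates to the corresponding module.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, Dataset
from .peaks import EmptySelectionError, bin_probe_responses, fit_peak
from .shifts import ShiftSummary, group_shift_summary
from .single_trial import (
    FilterRules,
    apply_trial_filters,
    fit_low_high_low,
    fits_to_frame,
)

FIT_COLUMNS = [
    "subject_id", "cue_id", "phase", "context", "B", "S", "PT", "SP", "K",
    "peak_time", "cv", "sse", "converged", "n_trials",
]


def peak_fit_table(
    dataset: Dataset,
    config: Optional[AnalysisConfig] = None,
    cues: Optional[Sequence[str]] = None,
    phases: Sequence[str] = ("train", "test"),
    fit_options: Optional[dict] = None,
) -> pd.DataFrame:
    """Fit every (subject, cue, phase, context) cell with probe trials.

    Cells with no qualifying probes are skipped silently (they surface as
    missing rows, matching reduced ns downstream).
    """
    config = config or AnalysisConfig()
    rows = []
    for subject in dataset.subjects:
        for phase in phases:
            for context in dataset.contexts(phase) or [None]:
                for cue in cues or dataset.cues(phase):
                    try:
                        pf = bin_probe_responses(
                            dataset, subject, cue, phase, config, context
                        )
                    except EmptySelectionError:
                        continue
                    fit = fit_peak(pf, fit_options)
                    rows.append(
                        {
                            "subject_id": subject,
                            "cue_id": cue,
                            "phase": phase,
                            "context": pf.context,
                            "B": fit.B,
                            "S": fit.S,
                            "PT": fit.PT,
                            "SP": fit.SP,
                            "K": fit.K,
                            "peak_time": fit.peak_time,
                            "cv": fit.cv,
                            "sse": fit.sse,
                            "converged": fit.converged,
                            "n_trials": fit.n_trials,
                        }
                    )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def shift_pairs(
    fits: pd.DataFrame,
    cue_id: str,
    measure: str = "peak_time",
    test_context: Optional[str] = None,
) -> pd.DataFrame:
    """Per-subject (train, test) value pairs for one cue and measure."""
    train = fits[(fits.cue_id == cue_id) & (fits.phase == "train")]
    test = fits[(fits.cue_id == cue_id) & (fits.phase == "test")]
    if test_context is not None:
        test = test[test.context == test_context]
    merged = train.merge(
        test, on=["subject_id", "cue_id"], suffixes=("_train", "_test")
    )
    out = merged[["subject_id", f"{measure}_train", f"{measure}_test"]].copy()
    out.columns = ["subject_id", "train_value", "test_value"]
    return out.sort_values("subject_id").reset_index(drop=True)


def cue_shift_summary(
    fits: pd.DataFrame,
    cue_id: str,
    measure: str = "peak_time",
    group: str = "",
    test_context: Optional[str] = None,
) -> ShiftSummary:
    pairs = shift_pairs(fits, cue_id, measure, test_context)
    return group_shift_summary(
        pairs.train_value, pairs.test_value,
        group=group or cue_id, measure=measure, subjects=list(pairs.subject_id),
    )


def shift_table(
    fits: pd.DataFrame,
    measures: Sequence[str] = ("peak_time", "cv"),
    group: str = "",
    test_context: Optional[str] = None,
) -> pd.DataFrame:
    """Tidy per-subject shift table across all cues with train+test fits."""
    rows = []
    cues = sorted(set(fits.cue_id))
    for cue in cues:
        for measure in measures:
            pairs = shift_pairs(fits, cue, measure, test_context)
            for r in pairs.itertuples(index=False):
                if r.train_value <= 0:
                    continue
                rows.append(
                    {
                        "group": group,
                        "cue_id": cue,
                        "measure": measure,
                        "subject_id": r.subject_id,
                        "train_value": r.train_value,
                        "test_value": r.test_value,
                        "pct_change": 100.0 * (r.test_value - r.train_value) / r.train_value,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["group", "cue_id", "measure", "subject_id",
                 "train_value", "test_value", "pct_change"],
    )


def single_trial_table(
    dataset: Dataset,
    fits: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    cues: Optional[Sequence[str]] = None,
    phases: Sequence[str] = ("train", "test"),
) -> pd.DataFrame:
    """Start/stop fits for every probe trial, filtered against session peaks.

    The straddle filter uses the peak time of the matching
    (subject, cue, phase) row in ``fits``; trials in cells without a peak
    fit are skipped.
    """
    config = config or AnalysisConfig()
    peak_lookup = {
        (r.subject_id, r.cue_id, r.phase): r.peak_time
        for r in fits.itertuples(index=False)
    }
    all_fits = []
    for subject in dataset.subjects:
        for phase in phases:
            for cue in cues or dataset.cues(phase):
                key = (subject, cue, phase)
                if key not in peak_lookup:
                    continue
                rules = FilterRules(
                    min_responses=config.min_responses,
                    straddle_peak=config.straddle_peak,
                    session_peak_time=peak_lookup[key],
                    early_response_cutoff=config.early_response_cutoff,
                )
                trials = dataset.select(
                    subject_id=subject, cue_id=cue, phase=phase, trial_type="probe"
                )
                st = [fit_low_high_low(t) for t in trials if t.n_responses >= 1]
                all_fits.extend(apply_trial_filters(st, rules))
    return fits_to_frame(all_fits)
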