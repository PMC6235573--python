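"""CSV readers/writers for the two-file trial/response format.

Layout (long format, one response per row in the second table):

``trials.csv``
    subject_id, group, context, phase, session, trial_index, cue_id,
    trial_type, programmed_duration_s, probe_duration_s (empty for fi),
    reinforced_time_s (empty for probe)

``responses.csv``
    subject_id, phase, session, trial_index, t_s

Responses join to trials on (subject_id, phase, session, trial_index).
Times are seconds from cue onset, written with 6 decimal places (the
acquisition resolution of operant rigs is ~1 ms, so 3+ decimals suffice).
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datamodel import (
    Dataset,
    IntegrityError,
    SchemaError,
    TrialRecord,
    ValidationError,
)

TRIAL_COLUMNS = [
    "subject_id", "group", "context", "phase", "session", "trial_index",
    "cue_id", "trial_type", "programmed_duration_s", "probe_duration_s",
    "reinforced_time_s",
]
RESPONSE_COLUMNS = ["subject_id", "phase", "session", "trial_index", "t_s"]

_KEY = ["subject_id", "phase", "session", "trial_index"]


def dataset_to_frames(dataset: Dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a :class:`Dataset` into (trials, responses) DataFrames."""
    trows = []
    rrows = []
    for t in dataset:
        trows.append(
            {
                "subject_id": t.subject_id,
                "group": t.group,
                "context": t.context,
                "phase": t.phase,
                "session": t.session,
                "trial_index": t.trial_index,
                "cue_id": t.cue_id,
                "trial_type": t.trial_type,
                "programmed_duration_s": t.programmed_duration,
                "probe_duration_s": t.probe_duration,
                "reinforced_time_s": t.reinforced_time,
            }
        )
        for ts in t.responses:
            rrows.append(
                {
                    "subject_id": t.subject_id,
                    "phase": t.phase,
                    "session": t.session,
                    "trial_index": t.trial_index,
                    "t_s": float(ts),
                }
            )
    trials = pd.DataFrame(trows, columns=TRIAL_COLUMNS)
    responses = pd.DataFrame(rrows, columns=RESPONSE_COLUMNS)
    return trials, responses


def write_dataset(
    dataset: Dataset,
    out_dir: Union[str, Path],
    trials_name: str = "trials.csv",
    responses_name: str = "responses.csv",
) -> tuple[Path, Path]:
    """Write ``trials.csv`` and ``responses.csv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials, responses = dataset_to_frames(dataset)
    tp = out / trials_name
    rp = out / responses_name
    trials.to_csv(tp, index=False, float_format="%.6f")
    responses.to_csv(rp, index=False, float_format="%.6f")
    return tp, rp


def frames_to_dataset(
    trials: pd.DataFrame,
    responses: pd.DataFrame,
    design_label: str = "",
    provenance: str = "",
) -> Dataset:
    """Join the two tables into a :class:`Dataset`, enforcing the contracts."""
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise SchemaError(f"trials table missing column {col!r}")
    for col in RESPONSE_COLUMNS:
        if col not in responses.columns:
            raise SchemaError(f"responses table missing column {col!r}")

    trials = trials.copy()
    trials["session"] = trials["session"].astype(int)
    trials["trial_index"] = trials["trial_index"].astype(int)

    dup = trials.duplicated(subset=_KEY)
    if dup.any():
        keys = trials.loc[dup, _KEY].itertuples(index=False, name=None)
        raise IntegrityError(f"duplicate trial keys: {sorted(set(keys))[:10]}")

    trial_keys = set(trials[_KEY].itertuples(index=False, name=None))
    grouped: dict[tuple, np.ndarray] = {}
    if len(responses):
        responses = responses.copy()
        responses["session"] = responses["session"].astype(int)
        responses["trial_index"] = responses["trial_index"].astype(int)
        rkeys = list(responses[_KEY].itertuples(index=False, name=None))
        orphans = sorted({k for k in rkeys if k not in trial_keys})
        if orphans:
            raise IntegrityError(
                f"responses reference {len(orphans)} nonexistent trial(s): {orphans[:10]}"
            )
        for k, grp in responses.groupby(_KEY, sort=False):
            grouped[k] = grp["t_s"].to_numpy(dtype=float)

    records = []
    for row in trials.itertuples(index=False):
        key = (row.subject_id, row.phase, row.session, row.trial_index)
        resp = grouped.get(key, np.empty(0))
        if resp.size and np.any(np.diff(resp) < 0):
            raise ValidationError(f"non-monotone response timestamps for trial {key}")
        records.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                context=str(row.context),
                phase=str(row.phase),
                session=int(row.session),
                trial_index=int(row.trial_index),
                cue_id=str(row.cue_id),
                trial_type=str(row.trial_type),
                programmed_duration=float(row.programmed_duration_s),
                probe_duration=_opt(row.probe_duration_s),
                reinforced_time=_opt(row.reinforced_time_s),
                responses=resp,
            )
        )
    return Dataset(trials=records, design_label=design_label, provenance=provenance)


def load_dataset(
    trials_path: Union[str, Path],
    responses_path: Union[str, Path],
    design_label: str = "",
) -> Dataset:
    """Read the two linked CSVs and return a validated-joinable Dataset.

    Trials with no matching response rows are retained with an empty
    response list (legal: they contribute zero-count bins downstream).
    """
    trials_path, responses_path = Path(trials_path), Path(responses_path)
    trials = pd.read_csv(trials_path)
    responses = pd.read_csv(responses_path)
    return frames_to_dataset(
        trials,
        responses,
        provenance=f"files:{trials_path}:{responses_path}",
    )


def _opt(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return float(x)


def write_manifest(path: Union[str, Path], payload: dict) -> Path:
    """Write a JSON run manifest (command, resolved config, seed, versions)."""
    import peakshift

    meta = {
        "peakshift_version": peakshift.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({**payload, "versions": meta}, fh, indent=2, sort_keys=True)
    return path
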