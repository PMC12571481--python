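"""On-disk containers: one HDF5 file per subject-session plus a CSV trial
table, and a JSON cohort manifest.

HDF5 layout::

    /roi/<name>/<task>/<period>    trials x voxels pattern matrix
    /timeseries/<task>_<run>/<roi> optional per-run voxel time series

Datasets are written with ``track_times=False`` so identical simulations
produce bit-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .patterns import PatternSet
from .synthgen import Cohort, SubjectDataset

TRIAL_CSV_SUFFIX = "_trials.csv"


def subject_basename(subject: str, session: str) -> str:
    return f"{subject}_{session}"


def write_subject(ds: SubjectDataset, directory: str | Path) -> dict[str, Path]:
    """Write one subject-session to ``<dir>/<subject>_<session>.h5`` and a
    trial-table CSV; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = subject_basename(ds.subject, ds.session)
    h5_path = directory / f"{base}.h5"
    csv_path = directory / f"{base}{TRIAL_CSV_SUFFIX}"
    with h5py.File(h5_path, "w") as f:
        f.attrs["subject"] = ds.subject
        f.attrs["session"] = ds.session
        f.attrs["propensity"] = ds.propensity
        f.attrs["accuracy"] = ds.accuracy
        for (roi, task, period), ps in sorted(ds.patterns.items()):
            grp = f.require_group(f"roi/{roi}/{task}")
            dset = grp.create_dataset(period, data=ps.matrix, track_times=False)
            dset.attrs["normalization_state"] = ps.normalization_state
        if ds.timeseries is not None:
            for (task, run), roi_ts in sorted(ds.timeseries.items()):
                grp = f.require_group(f"timeseries/{task}_{run}")
                for roi, arr in sorted(roi_ts.items()):
                    grp.create_dataset(roi, data=arr, track_times=False)
    ds.trials.to_csv(csv_path, index=False)
    if ds.events is not None:
        ds.events.to_csv(directory / f"{base}_events.csv", index=False)
    return {"h5": h5_path, "trials": csv_path}


def read_subject_patterns(
    directory: str | Path, subject: str, session: str
) -> dict[tuple[str, str, str], PatternSet]:
    """Load the pattern sets of one subject-session back into memory.

    Trial metadata rows are re-attached from the CSV trial table: attention
    patterns align with the attention trials (in stored order), perception
    patterns with the perception trials.
    """
    directory = Path(directory)
    base = subject_basename(subject, session)
    trials = pd.read_csv(directory / f"{base}{TRIAL_CSV_SUFFIX}")
    out: dict[tuple[str, str, str], PatternSet] = {}
    with h5py.File(directory / f"{base}.h5", "r") as f:
        for roi in f["roi"]:
            for task in f[f"roi/{roi}"]:
                for period in f[f"roi/{roi}/{task}"]:
                    dset = f[f"roi/{roi}/{task}/{period}"]
                    meta = trials[trials["task"] == task].reset_index(drop=True).copy()
                    meta["period"] = period
                    out[(roi, task, period)] = PatternSet(
                        roi=roi,
                        matrix=dset[()],
                        meta=meta,
                        normalization_state=dset.attrs.get(
                            "normalization_state", "raw"
                        ),
                    )
    return out


def write_manifest(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(cohort.manifest, f, indent=2, sort_keys=True)
        f.write("\n")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_default)
        f.write("\n")
    return path
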