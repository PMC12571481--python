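"""Trial-pattern construction: preprocessing, window extraction, trial
filtering and z-normalization.

The pipeline's universal currency is the :class:`PatternSet` — a trials x
voxels response matrix for one ROI with an aligned trial-metadata table.
Raw run time series become PatternSets by (1) linear detrending, discrete-
cosine high-pass filtering at 0.01 Hz and conversion to percent signal
change per run, (2) averaging the BOLD samples in a 2-s window 4-6 s after
the event of interest, (3) dropping runs with below-chance behavior and
trials that are short-delay or incorrect, and (4) z-normalizing each voxel
across the two conditions of a task/period group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

DEFAULT_HIGHPASS_HZ = 0.01
#: extraction window, seconds after event onset (half-open [4, 6))
DEFAULT_WINDOW = (4.0, 6.0)


@dataclass
class PatternSet:
    """Trials x voxels matrix for one ROI with aligned trial metadata."""

    roi: str
    matrix: np.ndarray
    meta: pd.DataFrame
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("pattern matrix must be 2-D (trials x voxels)")
        if len(self.meta) != self.matrix.shape[0]:
            raise ValueError(
                f"meta has {len(self.meta)} rows but matrix has {self.matrix.shape[0]} trials"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("pattern matrix contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    def select(self, mask: np.ndarray) -> "PatternSet":
        """Row-subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return PatternSet(
            roi=self.roi,
            matrix=self.matrix[mask],
            meta=self.meta.iloc[mask].reset_index(drop=True),
            normalization_state=self.normalization_state,
        )

    def condition(self, column: str, value) -> "PatternSet":
        return self.select((self.meta[column] == value).to_numpy())


@dataclass
class PreprocessedRun:
    data: np.ndarray
    kept_voxels: np.ndarray
    log: list[str] = field(default_factory=list)


def dct_highpass_basis(n_samples: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Orthonormal DCT-II regressors below the cutoff frequency.

    Basis function k (k >= 1) has frequency k / (2 * n * TR); all functions
    with frequency strictly below ``cutoff_hz`` are returned (constant term
    excluded — the mean is handled by detrending).
    """
    n = n_samples
    k_max = int(np.floor(2.0 * n * tr * cutoff_hz))
    t = np.arange(n)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n)) for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0, keepdims=True)


def dct_highpass(data: np.ndarray, tr: float, cutoff_hz: float = DEFAULT_HIGHPASS_HZ):
    """Remove slow drifts by regressing out the sub-cutoff DCT basis."""
    basis = dct_highpass_basis(data.shape[0], tr, cutoff_hz)
    if basis.shape[1] == 0:
        return data.copy()
    return data - basis @ (basis.T @ data)


def preprocess_run(
    ts: np.ndarray,
    tr: float,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    mean_tol: float = 1e-8,
) -> PreprocessedRun:
    """Detrend, high-pass filter and convert one run to percent signal change.

    Per voxel: subtract the best linear trend, remove discrete-cosine drift
    regressors below ``highpass_hz``, then scale the residual fluctuation by
    100 / (raw run mean). Voxels whose raw mean is ~0 cannot be expressed in
    percent signal change; they are excluded and logged.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    mean = ts.mean(axis=0)
    keep = np.abs(mean) > mean_tol
    log = []
    if not keep.all():
        bad = np.flatnonzero(~keep)
        log.append(f"excluded {bad.size} zero-mean voxel(s): {bad.tolist()}")
    data = ts[:, keep]
    data = scipy.signal.detrend(data, axis=0)
    data = dct_highpass(data, tr, highpass_hz)
    psc = 100.0 * data / mean[keep]
    return PreprocessedRun(data=psc, kept_voxels=np.flatnonzero(keep), log=log)


def extract_trial_patterns(
    ts: np.ndarray,
    tr: float,
    events: pd.DataFrame,
    roi: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
    onset_column: str = "onset",
) -> PatternSet:
    """Average the samples acquired in ``[onset + w0, onset + w1)`` per event.

    Sample i is taken to start at time i * TR (sample-onset convention); a
    sample belongs to the window when its onset lies in the half-open
    interval. With TR = 2 s and the default 4-6 s window this selects
    exactly one volume per event. An event with no samples in its window is
    an error naming the event.
    """
    ts = np.asarray(ts, dtype=float)
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must have positive length")
    sample_onsets = np.arange(ts.shape[0]) * tr
    rows = []
    for i, onset in enumerate(events[onset_column].to_numpy(dtype=float)):
        in_win = (sample_onsets >= onset + w0) & (sample_onsets < onset + w1)
        if not in_win.any():
            raise ValueError(
                f"event {i} (onset {onset:g}s) has no samples in window "
                f"[{onset + w0:g}, {onset + w1:g})"
            )
        rows.append(ts[in_win].mean(axis=0))
    return PatternSet(roi=roi, matrix=np.vstack(rows), meta=events.reset_index(drop=True))


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    dropped_runs: list
    counts_by_condition: dict


def filter_trials(
    ps: PatternSet, min_run_accuracy: float = 0.5
) -> tuple[PatternSet, FilterReport]:
    """Apply the behavioral trial-exclusion rules.

    Whole runs with accuracy below ``min_run_accuracy`` (computed over all
    trials of the run, before any trial-level exclusion) are dropped first.
    Attention trials are then kept only if long-delay and correct;
    perception trials only if correct. Idempotent: a filtered set passes
    through unchanged.
    """
    meta = ps.meta
    required = {"task", "run", "correct"}
    if not required.issubset(meta.columns):
        raise ValueError(f"meta must contain columns {sorted(required)}")
    run_acc = meta.groupby(["task", "run"])["correct"].mean()
    bad_runs = set(run_acc[run_acc < min_run_accuracy].index)
    keep = ~meta.apply(lambda r: (r["task"], r["run"]) in bad_runs, axis=1)
    is_att = meta["task"] == "attention"
    if is_att.any():
        if "delay" not in meta.columns:
            raise ValueError("attention trials require a 'delay' column")
        keep &= ~is_att | ((meta["delay"] == "long") & meta["correct"])
    keep &= is_att | meta["correct"].astype(bool)
    keep = keep.to_numpy()
    if not keep.any():
        raise ValueError("no trials survive filtering")
    out = ps.select(keep)
    counts = (
        out.meta.groupby(["task", "orientation"]).size().to_dict()
        if "orientation" in out.meta.columns
        else {}
    )
    report = FilterReport(
        n_input=ps.n_trials,
        n_retained=out.n_trials,
        dropped_runs=sorted(bad_runs),
        counts_by_condition={f"{k[0]}/{k[1]}": int(v) for k, v in counts.items()},
    )
    return out, report


def znormalize(ps: PatternSet, group_columns: tuple[str, ...] = ("task", "period")) -> PatternSet:
    """Z-score each voxel across all trials of each task/period group.

    Both orientation conditions are pooled within a group, so condition mean
    differences survive normalization. Population-SD convention (divide by
    n). A zero-variance voxel in any group is an error listing the voxels.
    """
    cols = [c for c in group_columns if c in ps.meta.columns]
    groups = (
        ps.meta.groupby(cols, dropna=False).indices.values()
        if cols
        else [np.arange(ps.n_trials)]
    )
    out = np.empty_like(ps.matrix)
    for idx in groups:
        idx = np.asarray(idx)
        if idx.size < 2:
            raise ValueError("z-normalization requires at least 2 trials per group")
        block = ps.matrix[idx]
        mean = block.mean(axis=0)
        sd = block.std(axis=0)  # population convention (ddof=0)
        dead = np.flatnonzero(sd <= 1e-10 * (np.abs(mean) + 1.0))
        if dead.size:
            raise ValueError(f"zero-variance voxel(s) in normalization group: {dead.tolist()}")
        out[idx] = (block - mean) / sd
    return replace(ps, matrix=out, meta=ps.meta.copy(), normalization_state="znormalized")
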