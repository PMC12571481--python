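"""Informational connectivity (IC) between ROIs.

IC asks whether trial-to-trial fluctuations of *pattern discriminability*
covary between regions — information-based coupling rather than coupling of
overall activation. Per ROI, a cross-validated trial-wise AMI series is
built: for every attention trial from one left-out run, the Mahalanobis
distance to the distribution of each attended orientation (estimated from
the remaining runs) gives a per-trial AMI. The concatenated series (all
trials in acquisition order) is then correlated between ROI pairs (Pearson)
and Fisher z-transformed. A control analysis applies the same correlation
to ROI-mean BOLD time courses, which is blind to pattern-level coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .decode import DEFAULT_SHRINKAGE
from .geometry import AMISeries, _chol_or_error, _mahalanobis_many, ami, pooled_reference_covariance
from .patterns import PatternSet

#: |r| is clipped here before atanh so degenerate series stay finite
FISHER_CLIP = 1.0 - 1e-6


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


@dataclass
class ICMatrix:
    """ROI x ROI informational-connectivity matrix (symmetric, diagonal
    masked with NaN)."""

    rois: tuple[str, ...]
    r: np.ndarray
    z: np.ndarray
    n_trials: int
    subject: str = ""
    session: str = ""
    period: str = "preparation"

    def pair(self, roi_a: str, roi_b: str) -> float:
        return float(self.z[self.rois.index(roi_a), self.rois.index(roi_b)])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                subject=self.subject,
                session=self.session,
                period=self.period,
                roi_a=a,
                roi_b=b,
                r=float(self.r[i, j]),
                z=float(self.z[i, j]),
                n_trials=self.n_trials,
            )
            for (i, a), (j, b) in combinations(enumerate(self.rois), 2)
        ]
        return pd.DataFrame(rows)


def trialwise_ami_crossval(
    ps: PatternSet,
    shrinkage: float = DEFAULT_SHRINKAGE,
    label_column: str = "orientation",
    run_column: str = "run",
) -> AMISeries:
    """Leave-one-run-out trial-wise AMI within the attention task.

    For each held-out run, reference distributions are the two attended-
    orientation conditions of the remaining runs (covariance pooled over
    both, shrinkage-regularized). D_same is the distance to the trial's own
    attention condition. The series is returned in acquisition order.
    """
    runs = sorted(pd.unique(ps.meta[run_column]))
    if len(runs) < 2:
        raise ValueError("cross-validated AMI requires at least 2 runs")
    labels = ps.meta[label_column].to_numpy()
    orients = sorted(pd.unique(labels))
    if len(orients) != 2:
        raise ValueError("need exactly two attention conditions")
    values = np.full(ps.n_trials, np.nan)
    for run in runs:
        test_mask = (ps.meta[run_column] == run).to_numpy()
        train_labels = labels[~test_mask]
        refs = {o: ps.matrix[~test_mask][train_labels == o] for o in orients}
        for o, m in refs.items():
            if m.shape[0] < 2:
                raise ValueError(f"fold for held-out run {run!r} lacks condition {o!r}")
        cov = pooled_reference_covariance(refs, shrinkage)
        chol = _chol_or_error(cov, shrinkage)
        dists = {
            o: _mahalanobis_many(ps.matrix[test_mask], refs[o].mean(axis=0), chol)
            for o in orients
        }
        test_labels = labels[test_mask]
        fold_vals = np.empty(test_labels.size)
        for i, lab in enumerate(test_labels):
            other = orients[1] if lab == orients[0] else orients[0]
            fold_vals[i] = ami(dists[lab][i], dists[other][i])
        values[test_mask] = fold_vals
    order = np.lexsort(
        (ps.meta["trial_index_in_run"].to_numpy(), ps.meta[run_column].to_numpy())
    )
    return AMISeries(
        values=values[order],
        trial_ids=ps.meta.iloc[order][[run_column, "trial_index_in_run"]].reset_index(
            drop=True
        ),
        roi=ps.roi,
        scheme="attention_crossval",
    )


def informational_connectivity(series_by_roi: dict[str, AMISeries]) -> ICMatrix:
    """Pairwise Pearson correlation of aligned AMI series, Fisher
    z-transformed. Series must agree trial-for-trial on their identifiers."""
    rois = tuple(series_by_roi)
    if len(rois) < 2:
        raise ValueError("connectivity needs at least two ROIs")
    first = series_by_roi[rois[0]]
    for roi in rois[1:]:
        s = series_by_roi[roi]
        if len(s) != len(first) or not s.trial_ids.equals(first.trial_ids):
            raise ValueError(f"AMI series for {roi!r} is misaligned with {rois[0]!r}")
    data = np.vstack([series_by_roi[r].values for r in rois])
    if np.any(data.std(axis=1) == 0):
        flat = [r for r, row in zip(rois, data) if row.std() == 0]
        raise ValueError(f"zero-variance AMI series for ROI(s): {flat}")
    r = np.corrcoef(data)
    z = fisher_z(r)
    np.fill_diagonal(r, np.nan)
    np.fill_diagonal(z, np.nan)
    return ICMatrix(rois=rois, r=r, z=z, n_trials=len(first))


def mean_bold_connectivity(ts_by_roi: dict[str, list[np.ndarray]]) -> ICMatrix:
    """Control connectivity from ROI-mean BOLD time courses.

    Per ROI the voxel-mean time course of each run is concatenated (same
    run order everywhere); pairs are correlated with Pearson and Fisher
    z-transformed.
    """
    rois = tuple(ts_by_roi)
    if len(rois) < 2:
        raise ValueError("connectivity needs at least two ROIs")
    courses = {}
    for roi, run_list in ts_by_roi.items():
        courses[roi] = np.concatenate(
            [np.asarray(run).mean(axis=1) if np.asarray(run).ndim == 2 else np.asarray(run)
             for run in run_list]
        )
    lengths = {roi: c.size for roi, c in courses.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"ROI mean time courses are misaligned: {lengths}")
    data = np.vstack([courses[r] for r in rois])
    if np.any(data.std(axis=1) == 0):
        flat = [r for r, row in zip(rois, data) if row.std() == 0]
        raise ValueError(f"zero-variance mean time course for ROI(s): {flat}")
    r = np.corrcoef(data)
    z = fisher_z(r)
    np.fill_diagonal(r, np.nan)
    np.fill_diagonal(z, np.nan)
    return ICMatrix(rois=rois, r=r, z=z, n_trials=data.shape[1])
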