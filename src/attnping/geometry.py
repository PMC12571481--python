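"""Representational geometry: Mahalanobis distances between attention and
perception conditions, and the attentional modulation index (AMI).

For each attention trial the Mahalanobis distance is computed to the
distribution of each perceived orientation (reference trials from the
perception task). Averaging within each attended x perceived orientation
pair gives a 2x2 distance table; collapsing it by orientation consistency
gives D_same (matched pairs) and D_different (mismatched pairs) and

    AMI = (D_different - D_same) / (D_different + D_same),

positive when activity patterns sit closer to the matching perceived
orientation — the signature of a sensory-like attentional template. The
covariance used in the distance is pooled over the two reference
conditions (each centered on its own mean) with the same shrinkage
regularization as the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import DEFAULT_SHRINKAGE
from .patterns import PatternSet


@dataclass
class DistanceTable:
    """Mean Mahalanobis distances for each attended x perceived pair."""

    cells: dict[tuple[str, str], float]  # (attended, perceived) -> mean distance
    d_same: float
    d_different: float
    ami: float
    roi: str = ""
    subject: str = ""
    session: str = ""
    period: str = "preparation"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                subject=self.subject,
                session=self.session,
                roi=self.roi,
                period=self.period,
                attended=a,
                perceived=p,
                distance=d,
            )
            for (a, p), d in self.cells.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class AMISeries:
    """Trial-ordered AMI values for one ROI."""

    values: np.ndarray
    trial_ids: pd.DataFrame  # run, trial_index_in_run (acquisition order)
    roi: str
    scheme: str  # "perception_ref" or "attention_crossval"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.trial_ids) != self.values.size:
            raise ValueError("trial_ids and values are misaligned")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AMI series contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


def pooled_reference_covariance(
    refs: dict[str, np.ndarray], alpha: float = DEFAULT_SHRINKAGE
) -> np.ndarray:
    """Covariance pooled over reference conditions, each centered on its own
    mean, shrunk toward a scaled identity: (1-a) S + a (tr S / V) I."""
    mats = list(refs.values())
    V = mats[0].shape[1]
    n = sum(m.shape[0] for m in mats)
    if n - len(mats) < 1:
        raise ValueError("reference distributions need at least 2 trials in total")
    scatter = np.zeros((V, V))
    for m in mats:
        c = m - m.mean(axis=0)
        scatter += c.T @ c
    S = scatter / max(n - len(mats), 1)
    return (1.0 - alpha) * S + alpha * (np.trace(S) / V) * np.eye(V)


def _chol_or_error(cov: np.ndarray, alpha: float) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "reference covariance is singular"
            + ("; set shrinkage > 0 to regularize" if alpha == 0 else "")
        ) from exc
    return chol


def mahalanobis_to_distribution(
    x: np.ndarray,
    ref: np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
    cov: np.ndarray | None = None,
) -> float:
    """sqrt((x - mean(ref))' Cov^-1 (x - mean(ref))).

    By default the covariance is estimated from ``ref`` itself (with
    shrinkage); pass ``cov`` to use a covariance pooled over several
    reference conditions.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if ref.ndim != 2 or ref.shape[0] < 2:
        raise ValueError("reference needs at least 2 trials")
    if x.shape[-1] != ref.shape[1]:
        raise ValueError("dimension mismatch between pattern and reference")
    if cov is None:
        cov = pooled_reference_covariance({"ref": ref}, shrinkage)
    chol = _chol_or_error(cov, shrinkage)
    delta = x - ref.mean(axis=0)
    y = np.linalg.solve(chol, np.atleast_2d(delta).T)
    d = np.sqrt(np.sum(y**2, axis=0))
    return float(d[0]) if x.ndim == 1 else d


def _mahalanobis_many(X: np.ndarray, mu: np.ndarray, chol: np.ndarray) -> np.ndarray:
    y = np.linalg.solve(chol, (X - mu).T)
    return np.sqrt(np.sum(y**2, axis=0))


def ami(d_same: float, d_different: float) -> float:
    """(D_different - D_same) / (D_different + D_same); requires a positive
    denominator (two zero distances leave the index undefined)."""
    if d_same < 0 or d_different < 0:
        raise ValueError("distances must be non-negative")
    total = d_same + d_different
    if total == 0:
        raise ValueError("AMI undefined: both distances are zero")
    return (d_different - d_same) / total


def distance_table(
    prep: PatternSet,
    perc: PatternSet,
    shrinkage: float = DEFAULT_SHRINKAGE,
    label_column: str = "orientation",
    period: str = "preparation",
) -> DistanceTable:
    """The 2x2 attended x perceived Mahalanobis distance table.

    Every attention trial is measured against both perception
    distributions; cells average over the trials of one attended
    orientation. The covariance is pooled over the two perception
    conditions.
    """
    att_labels = prep.meta[label_column].to_numpy()
    perc_labels = perc.meta[label_column].to_numpy()
    orientations = sorted(pd.unique(perc_labels))
    if len(orientations) != 2:
        raise ValueError("need exactly two perceived orientations")
    refs = {o: perc.matrix[perc_labels == o] for o in orientations}
    for o, m in refs.items():
        if m.shape[0] < 2:
            raise ValueError(f"perception condition {o!r} has fewer than 2 trials")
    cov = pooled_reference_covariance(refs, shrinkage)
    chol = _chol_or_error(cov, shrinkage)
    cells = {}
    for a in sorted(pd.unique(att_labels)):
        block = prep.matrix[att_labels == a]
        if block.shape[0] == 0:
            raise ValueError(f"attention condition {a!r} is empty")
        for p in orientations:
            cells[(a, p)] = float(
                np.mean(_mahalanobis_many(block, refs[p].mean(axis=0), chol))
            )
    if len(cells) != 4:
        raise ValueError("distance table requires both conditions in both tasks")
    d_same = float(np.mean([cells[(o, o)] for o in orientations]))
    d_diff = float(
        np.mean([cells[(a, p)] for a in orientations for p in orientations if a != p])
    )
    meta = prep.meta
    return DistanceTable(
        cells=cells,
        d_same=d_same,
        d_different=d_diff,
        ami=ami(d_same, d_diff),
        roi=prep.roi,
        subject=str(meta["subject"].iloc[0]) if "subject" in meta.columns else "",
        session=str(meta["session"].iloc[0]) if "session" in meta.columns else "",
        period=period,
    )


def trialwise_ami(
    ps: PatternSet,
    refs: dict[str, np.ndarray],
    shrinkage: float = DEFAULT_SHRINKAGE,
    label_column: str = "orientation",
    scheme: str = "perception_ref",
) -> AMISeries:
    """Per-trial AMI from a trial's distances to the same- and different-
    orientation reference distributions (acquisition order preserved)."""
    if len(refs) != 2 or not set(pd.unique(ps.meta[label_column])) <= set(refs):
        raise ValueError("need exactly two references covering the trial labels")
    cov = pooled_reference_covariance(refs, shrinkage)
    chol = _chol_or_error(cov, shrinkage)
    labels = ps.meta[label_column].to_numpy()
    orients = sorted(refs)
    dists = {o: _mahalanobis_many(ps.matrix, refs[o].mean(axis=0), chol) for o in orients}
    values = np.empty(ps.n_trials)
    for i, lab in enumerate(labels):
        other = orients[1] if lab == orients[0] else orients[0]
        values[i] = ami(dists[lab][i], dists[other][i])
    id_cols = [c for c in ("run", "trial_index_in_run") if c in ps.meta.columns]
    return AMISeries(
        values=values,
        trial_ids=ps.meta[id_cols].reset_index(drop=True),
        roi=ps.roi,
        scheme=scheme,
    )


@dataclass
class TrialSort:
    """Top/bottom AMI-quantile trial groups with behavioral summaries."""

    strong_index: np.ndarray
    weak_index: np.ndarray
    strong_rt: float
    weak_rt: float
    strong_accuracy: float
    weak_accuracy: float
    n_per_group: int


def sort_trials_by_ami(
    series: AMISeries, behavior: pd.DataFrame, q: float = 0.25
) -> TrialSort:
    """Sort trials by AMI (descending); the top floor(qN) are the 'strong
    modulation' group and the bottom floor(qN) the 'weak' group."""
    if not 0.0 < q <= 0.5:
        raise ValueError("quantile fraction q must lie in (0, 0.5]")
    if len(behavior) != len(series):
        raise ValueError("behavior table and AMI series are misaligned")
    n = len(series)
    k = int(np.floor(q * n))
    if k == 0:
        raise ValueError(f"q={q} with {n} trials selects no trials")
    order = np.argsort(-series.values, kind="stable")
    strong, weak = order[:k], order[n - k :]
    rt = behavior["rt"].to_numpy(dtype=float)
    acc = behavior["correct"].to_numpy(dtype=float)
    return TrialSort(
        strong_index=strong,
        weak_index=weak,
        strong_rt=float(rt[strong].mean()),
        weak_rt=float(rt[weak].mean()),
        strong_accuracy=float(acc[strong].mean()),
        weak_accuracy=float(acc[weak].mean()),
        n_per_group=k,
    )
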