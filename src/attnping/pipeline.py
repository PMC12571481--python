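"""End-to-end analysis of a simulated cohort, plus stage orchestration.

``analyze_cohort`` is the in-memory workhorse: it filters and z-normalizes
every subject's patterns, runs leave-one-run-out attention decoding and
perception-to-attention generalization with permutation nulls, aggregates
group-level significance (null distributions averaged across subjects,
95th-percentile rule, Bonferroni over ROIs), computes the Mahalanobis
distance tables / AMI, the trial-wise AMI series and informational
connectivity, and the AMI-behavior couplings.

The :class:`Pipeline` class wraps the same computation as file-based stages
(simulate -> decode -> geometry -> connect -> infer) with a content-hash
manifest for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as apio
from .config import AnalysisBlock, PipelineConfig
from .connectivity import informational_connectivity, trialwise_ami_crossval
from .decode import cross_task_generalize, loro_decode
from .geometry import distance_table, sort_trials_by_ami, trialwise_ami
from .inference import (
    NullDistribution,
    bonferroni,
    group_null,
    neural_behavior_correlation,
    permutation_null,
    permutation_pvalue,
)
from .patterns import PatternSet, filter_trials, znormalize
from .synthgen import Cohort, SimConfig, SubjectDataset, simulate_cohort

SCHEMES = ("attention_loro", "generalization_preparation", "generalization_selection")


# ---------------------------------------------------------------------------
# per-subject preparation and analysis
# ---------------------------------------------------------------------------


def prepare_subject(
    patterns: dict[tuple[str, str, str], PatternSet],
    analysis: AnalysisBlock | None = None,
) -> dict[str, dict[str, PatternSet]]:
    """Filter and z-normalize one subject's pattern sets.

    Returns {roi: {"preparation": ps, "selection": ps, "perception": ps}}
    with behavioral exclusions applied (long-delay correct attention trials;
    correct perception trials; sub-50%-accuracy runs dropped whole) and each
    task/period group z-normalized across its pooled conditions.
    """
    analysis = analysis or AnalysisBlock()
    rois = sorted({roi for roi, _, _ in patterns})
    out: dict[str, dict[str, PatternSet]] = {}
    for roi in rois:
        entry = {}
        for task, period in (
            ("attention", "preparation"),
            ("attention", "selection"),
            ("perception", "perception"),
        ):
            ps = patterns[(roi, task, period)]
            filtered, _ = filter_trials(ps, analysis.min_run_accuracy)
            entry[period] = znormalize(filtered)
        out[roi] = entry
    return out


@dataclass
class SubjectDecoding:
    subject: str
    session: str
    roi: str
    scheme: str
    accuracy: float
    null: NullDistribution


def decode_subject(
    prepared: dict[str, dict[str, PatternSet]],
    subject: str,
    session: str,
    analysis: AnalysisBlock,
    seed: int,
    schemes: tuple[str, ...] = SCHEMES,
) -> list[SubjectDecoding]:
    """All decoding schemes with their permutation nulls for one subject."""
    results = []
    for r_idx, (roi, sets) in enumerate(sorted(prepared.items())):
        for s_idx, scheme in enumerate(schemes):
            child = (seed * 5003 + 97 * r_idx + s_idx) % (2**31)
            if scheme == "attention_loro":
                res = loro_decode(sets["preparation"], analysis.shrinkage)
                null = permutation_null(
                    sets["preparation"],
                    "within_task_loro",
                    analysis.n_perm,
                    child,
                    shrinkage=analysis.shrinkage,
                )
            else:
                period = scheme.split("_", 1)[1]
                res = cross_task_generalize(
                    sets["perception"], sets[period], period, analysis.shrinkage
                )
                null = permutation_null(
                    sets["perception"],
                    "cross_task",
                    analysis.n_perm,
                    child,
                    test=sets[period],
                    period=period,
                    shrinkage=analysis.shrinkage,
                )
            results.append(
                SubjectDecoding(
                    subject=subject,
                    session=session,
                    roi=roi,
                    scheme=scheme,
                    accuracy=res.pooled_accuracy,
                    null=null,
                )
            )
    return results


# ---------------------------------------------------------------------------
# cohort-level analysis
# ---------------------------------------------------------------------------


@dataclass
class CohortResults:
    subject_decoding: pd.DataFrame
    group_decoding: pd.DataFrame
    geometry: pd.DataFrame
    behavior: pd.DataFrame
    connectivity: pd.DataFrame
    correlations: dict = field(default_factory=dict)
    nulls: dict = field(default_factory=dict)
    ami_trials: pd.DataFrame = field(default_factory=pd.DataFrame)
    filtering: pd.DataFrame = field(default_factory=pd.DataFrame)


def group_decoding_table(
    subject_results: list[SubjectDecoding], alpha: float = 0.05
) -> pd.DataFrame:
    """Group-mean accuracy, group permutation p (add-one rule), threshold
    significance and Bonferroni adjustment across ROIs per session/scheme."""
    rows = []
    by_key: dict[tuple, list[SubjectDecoding]] = {}
    for r in subject_results:
        by_key.setdefault((r.session, r.scheme, r.roi), []).append(r)
    for (session, scheme, roi), rs in sorted(by_key.items()):
        gnull = group_null([r.null for r in rs])
        observed = float(np.mean([r.accuracy for r in rs]))
        test = permutation_pvalue(observed, gnull, alpha)
        rows.append(
            dict(
                session=session,
                scheme=scheme,
                roi=roi,
                n_subjects=len(rs),
                accuracy=observed,
                p_value=test.p_value,
                threshold_95=test.threshold_95,
                significant=test.significant,
            )
        )
    out = pd.DataFrame(rows)
    # Bonferroni across the ROIs tested within each session x scheme family
    adj = []
    for (_, _), block in out.groupby(["session", "scheme"], sort=False):
        p_adj = bonferroni(block["p_value"].to_numpy())
        adj.append(pd.Series(p_adj, index=block.index))
    out["p_bonferroni"] = pd.concat(adj).sort_index()
    out["significant_bonferroni"] = out["p_bonferroni"] < 0.05
    return out


def analyze_cohort(
    cohort: Cohort,
    analysis: AnalysisBlock | None = None,
    seed: int = 0,
    include: tuple[str, ...] = ("decoding", "geometry", "connectivity", "behavior"),
    behavior_roi: str = "V1",
) -> CohortResults:
    """Run the full multivariate analysis battery on a simulated cohort."""
    analysis = analysis or AnalysisBlock()
    subj_rows: list[SubjectDecoding] = []
    geom_rows, behav_rows, ic_frames = [], [], []
    ami_frames, filter_rows = [], []
    sessions = sorted({s for s, _ in cohort.datasets})
    for ses in sessions:
        for subj_idx, sid in enumerate(cohort.subjects(ses)):
            ds = cohort.get(ses, sid)
            prepared = prepare_subject(ds.patterns, analysis)
            # filtering depends on trial metadata only, so one ROI's report
            # audits the whole subject-session
            _, rep = filter_trials(
                ds.patterns[(behavior_roi, "attention", "preparation")],
                analysis.min_run_accuracy,
            )
            filter_rows.append(
                dict(
                    subject=sid,
                    session=ses,
                    n_input=rep.n_input,
                    n_retained=rep.n_retained,
                    dropped_runs=";".join(str(r) for r in rep.dropped_runs),
                    **rep.counts_by_condition,
                )
            )
            if "decoding" in include:
                child = (seed * 7919 + 31 * subj_idx + sessions.index(ses)) % (2**31)
                subj_rows.extend(
                    decode_subject(prepared, sid, ses, analysis, child)
                )
            if "geometry" in include or "behavior" in include:
                for roi, sets in sorted(prepared.items()):
                    for period in ("preparation", "selection"):
                        tab = distance_table(
                            sets[period],
                            sets["perception"],
                            analysis.shrinkage,
                            period=period,
                        )
                        geom_rows.append(
                            dict(
                                subject=sid,
                                session=ses,
                                roi=roi,
                                period=period,
                                d_same=tab.d_same,
                                d_different=tab.d_different,
                                ami=tab.ami,
                            )
                        )
            if "behavior" in include:
                sets = prepared[behavior_roi]
                prep = sets["preparation"]
                refs = {
                    o: sets["perception"]
                    .condition("orientation", o)
                    .matrix
                    for o in sorted(prep.meta["orientation"].unique())
                }
                series = trialwise_ami(prep, refs, analysis.shrinkage)
                ami_frames.append(
                    series.trial_ids.assign(
                        subject=sid, session=ses, roi=behavior_roi,
                        scheme=series.scheme, ami=series.values,
                    )
                )
                sort = sort_trials_by_ami(series, prep.meta, analysis.quantile)
                tab_ami = next(
                    g["ami"]
                    for g in geom_rows
                    if g["subject"] == sid
                    and g["session"] == ses
                    and g["roi"] == behavior_roi
                    and g["period"] == "preparation"
                )
                behav_rows.append(
                    dict(
                        subject=sid,
                        session=ses,
                        ami=tab_ami,
                        mean_trial_ami=float(series.values.mean()),
                        mean_rt=float(prep.meta["rt"].mean()),
                        accuracy=float(ds.accuracy),
                        strong_rt=sort.strong_rt,
                        weak_rt=sort.weak_rt,
                        strong_accuracy=sort.strong_accuracy,
                        weak_accuracy=sort.weak_accuracy,
                    )
                )
            if "connectivity" in include:
                series_by_roi = {
                    roi: trialwise_ami_crossval(
                        prepared[roi]["preparation"], analysis.shrinkage
                    )
                    for roi in sorted(prepared)
                }
                icm = informational_connectivity(series_by_roi)
                icm.subject, icm.session = sid, ses
                ic_frames.append(icm.to_frame())

    subject_decoding = pd.DataFrame(
        [
            dict(
                subject=r.subject,
                session=r.session,
                roi=r.roi,
                scheme=r.scheme,
                accuracy=r.accuracy,
            )
            for r in subj_rows
        ]
    )
    group = (
        group_decoding_table(subj_rows, analysis.alpha)
        if subj_rows
        else pd.DataFrame()
    )
    behavior = pd.DataFrame(behav_rows)
    correlations = {}
    if len(behavior):
        for ses, block in behavior.groupby("session"):
            if len(block) >= 3:
                r, p = neural_behavior_correlation(
                    block.set_index("subject")["ami"],
                    block.set_index("subject")["mean_rt"],
                )
                correlations[ses] = {
                    "ami_rt_r": r,
                    "ami_rt_p": p,
                    "strong_minus_weak_rt": float(
                        (block["strong_rt"] - block["weak_rt"]).mean()
                    ),
                }
    nulls = {(r.session, r.subject, r.roi, r.scheme): r.null for r in subj_rows}
    return CohortResults(
        subject_decoding=subject_decoding,
        group_decoding=group,
        geometry=pd.DataFrame(geom_rows),
        behavior=behavior,
        connectivity=pd.concat(ic_frames, ignore_index=True)
        if ic_frames
        else pd.DataFrame(),
        correlations=correlations,
        nulls=nulls,
        ami_trials=pd.concat(ami_frames, ignore_index=True)
        if ami_frames
        else pd.DataFrame(),
        filtering=pd.DataFrame(filter_rows),
    )


# ---------------------------------------------------------------------------
# file-based stage orchestration
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


STAGES = ("simulate", "decode", "geometry", "connect", "infer")


class Pipeline:
    """Config-driven stage runner with a content-hash manifest.

    Every stage records its output files and their sha256 digests in
    ``manifest.json``; rerunning a completed stage with an unchanged config
    is a no-op, and identical config+seed reruns produce identical hashes.
    """

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"config_hash": self._config_hash(), "stages": {}}
        )
        if self.manifest.get("config_hash") != self._config_hash():
            self.manifest = {"config_hash": self._config_hash(), "stages": {}}
        self._cohort: Cohort | None = None
        self._results: CohortResults | None = None

    def _config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest()

    def _record(self, stage: str, paths: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            str(p.relative_to(self.outdir)): _sha256(p) for p in sorted(paths)
        }
        self.manifest_path.write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )

    def _stage_complete(self, stage: str) -> bool:
        rec = self.manifest["stages"].get(stage)
        if not rec:
            return False
        for rel, digest in rec.items():
            p = self.outdir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    @property
    def cohort(self) -> Cohort:
        if self._cohort is None:
            sim: SimConfig = self.config.sim.to_sim_config(self.config.seed)
            self._cohort = simulate_cohort(
                sim, self.config.effects.to_effect_params(), seed=self.config.seed
            )
        return self._cohort

    def _ensure_results(self, include) -> CohortResults:
        if self._results is None:
            self._results = analyze_cohort(
                self.cohort,
                self.config.analysis,
                seed=self.config.seed,
                include=("decoding", "geometry", "connectivity", "behavior"),
            )
        return self._results

    def simulate(self, force: bool = False) -> list[Path]:
        if not force and self._stage_complete("simulate"):
            return []
        paths = []
        data_dir = self.outdir / "data"
        for (_, _), ds in sorted(self.cohort.datasets.items()):
            written = apio.write_subject(ds, data_dir)
            paths.extend(written.values())
        paths.append(apio.write_manifest(self.cohort, data_dir / "cohort.json"))
        self._record("simulate", paths)
        return paths

    def _write_table(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        return path

    def decode(self, force: bool = False) -> list[Path]:
        if not force and self._stage_complete("decode"):
            return []
        res = self._ensure_results(("decoding",))
        paths = [
            self._write_table(res.subject_decoding, "decoding_subjects.csv"),
            self._write_table(res.filtering, "filtering_report.csv"),
        ]
        self._record("decode", paths)
        return paths

    def geometry(self, force: bool = False) -> list[Path]:
        if not force and self._stage_complete("geometry"):
            return []
        res = self._ensure_results(("geometry", "behavior"))
        paths = [
            self._write_table(res.geometry, "distances.csv"),
            self._write_table(res.behavior, "behavior.csv"),
            self._write_table(res.ami_trials, "ami_trials.csv"),
        ]
        self._record("geometry", paths)
        return paths

    def connect(self, force: bool = False) -> list[Path]:
        if not force and self._stage_complete("connect"):
            return []
        res = self._ensure_results(("connectivity",))
        paths = [self._write_table(res.connectivity, "connectivity.csv")]
        self._record("connect", paths)
        return paths

    def infer(self, force: bool = False) -> list[Path]:
        if not force and self._stage_complete("infer"):
            return []
        res = self._ensure_results(("decoding",))
        paths = [
            self._write_table(res.group_decoding, "group_decoding.csv"),
            apio.write_json(res.correlations, self.outdir / "correlations.json"),
            self._write_nulls(res.nulls),
        ]
        self._record("infer", paths)
        return paths

    def _write_nulls(self, nulls: dict) -> Path:
        import h5py

        path = self.outdir / "null_distributions.h5"
        with h5py.File(path, "w") as f:
            for (session, subject, roi, scheme), nd in sorted(nulls.items()):
                grp = f.require_group(f"{session}/{subject}/{roi}")
                dset = grp.create_dataset(scheme, data=nd.values, track_times=False)
                dset.attrs["seed"] = -1 if nd.seed is None else nd.seed
                dset.attrs["level"] = nd.level
        return path

    def run(self, stages: tuple[str, ...] = STAGES, force: bool = False) -> dict:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for stage in STAGES:
            if stage in stages:
                getattr(self, stage if stage != "simulate" else "simulate")(force)
        return self.manifest
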