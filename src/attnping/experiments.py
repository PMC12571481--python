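"""Validation experiments: recovery of the generative effects by the full
analysis pipeline, and calibration of the permutation inference.

Each function simulates fresh data under stated conditions, runs the
ordinary analysis path, and summarizes how well the known ground truth is
recovered. They are used by the acceptance tests and by
``scripts/acceptance.py``; problem sizes are chosen to run on one CPU in
minutes (see the methods note for the rationale behind each design).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisBlock
from .connectivity import (
    informational_connectivity,
    mean_bold_connectivity,
    trialwise_ami_crossval,
)
from .decode import cross_task_generalize
from .geometry import distance_table, sort_trials_by_ami, trialwise_ami
from .inference import group_null, neural_behavior_correlation, permutation_null, permutation_pvalue
from .patterns import filter_trials, znormalize
from .pipeline import analyze_cohort, prepare_subject
from .synthgen import (
    EffectParams,
    SimConfig,
    emit_timeseries,
    make_ground_truth,
    simulate_cohort,
    simulate_subject,
)


def _seed(master: int, *key: int) -> int:
    out = int(master) % (2**31)
    for k in key:
        out = (out * 1000003 + int(k) + 1) % (2**31)
    return out


def _prep_set(ds, roi: str = "V1"):
    ps, _ = filter_trials(ds.pattern_set(roi, "attention", "preparation"))
    return znormalize(ps)


def _perc_set(ds, roi: str = "V1"):
    ps, _ = filter_trials(ds.pattern_set(roi, "perception", "perception"))
    return znormalize(ps)


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------


def permutation_calibration(
    n_experiments: int = 500,
    n_perm: int = 200,
    n_subjects: int = 6,
    seed: int = 0,
) -> dict:
    """Type-I error rate of the group-level permutation test on cohorts with
    no preparatory signal (beta_att = 0, lambda = 0).

    The tested effect is perception-to-preparation generalization — the
    scheme for which the train-label shuffle is exactly exchangeable with
    the observed statistic (see the methods note) — so the rejection rate
    of the 95th-percentile rule should sit at ~5%. Perception-task signal
    is left at its default: the null concerns the preparation period only,
    matching the scientific null hypothesis.
    """
    cfg_kw = dict(
        n_subjects_per_session=n_subjects, n_shared_subjects=0, n_voxels=16,
        rois=("V1",), n_attention_runs=4, n_perception_runs=2,
        trials_per_attention_run=12, trials_per_perception_run=12,
    )
    eff = EffectParams(beta_att=0.0, lam_default=0.0,
                       accuracy_mean=0.85, accuracy_sd=0.02)
    rejections = 0
    for e in range(n_experiments):
        obs, nulls = [], []
        for i in range(n_subjects):
            cfg = SimConfig(seed=_seed(seed, e, i), **cfg_kw)
            gt = make_ground_truth(cfg, eff, seed=_seed(seed, 1, e, i))
            ds = simulate_subject(gt, cfg, "NoPing", f"S{i}", seed=_seed(seed, 2, e, i))
            prep, perc = _prep_set(ds), _perc_set(ds)
            obs.append(
                cross_task_generalize(perc, prep, "preparation", 0.1).pooled_accuracy
            )
            nulls.append(
                permutation_null(perc, "cross_task", n_perm, _seed(seed, 3, e, i),
                                 test=prep, period="preparation")
            )
        test = permutation_pvalue(float(np.mean(obs)), group_null(nulls))
        rejections += int(test.significant)
    return {
        "rejection_rate": rejections / n_experiments,
        "n_experiments": n_experiments,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# dual-format recovery
# ---------------------------------------------------------------------------

EXPECTED_SIGNATURE = {
    # scheme -> {(session, roi): should the group test be significant?}
    "attention_loro": {(s, r): True for s in ("NoPing", "Ping")
                       for r in ("V1", "EVC", "IPS", "PFC")},
    "generalization_selection": {(s, r): True for s in ("NoPing", "Ping")
                                 for r in ("V1", "EVC", "IPS", "PFC")},
    "generalization_preparation": {
        **{("NoPing", r): False for r in ("V1", "EVC", "IPS", "PFC")},
        ("Ping", "V1"): True, ("Ping", "EVC"): True,
        ("Ping", "IPS"): False, ("Ping", "PFC"): False,
    },
}


def cohort_signature(group_table: pd.DataFrame) -> tuple[bool, dict]:
    """Compare a cohort's Bonferroni-corrected group results against the
    expected dual-format pattern."""
    detail = {}
    ok = True
    for _, row in group_table.iterrows():
        expected = EXPECTED_SIGNATURE[row["scheme"]][(row["session"], row["roi"])]
        got = bool(row["significant_bonferroni"])
        detail[(row["scheme"], row["session"], row["roi"])] = (expected, got)
        ok &= got == expected
    return ok, detail


def dual_format_recovery(
    n_cohorts: int = 20,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Rate at which full cohorts reproduce the dual-format signature:
    attended orientation decodable everywhere in both arms; perception
    patterns generalize to preparation only in V1/EVC of the Ping arm; and
    to stimulus selection everywhere."""
    analysis = AnalysisBlock(n_perm=n_perm)
    passes, tables = [], []
    for c in range(n_cohorts):
        cohort = simulate_cohort(SimConfig(seed=_seed(seed, 10, c)), EffectParams(),
                                 seed=_seed(seed, 10, c))
        res = analyze_cohort(cohort, analysis, seed=_seed(seed, 11, c),
                             include=("decoding",))
        ok, _ = cohort_signature(res.group_decoding)
        passes.append(ok)
        tables.append(res.group_decoding.assign(cohort=c))
    table = pd.concat(tables, ignore_index=True)
    mean_acc = table.groupby(["scheme", "session", "roi"])["accuracy"].mean()
    return {
        "recovery_rate": float(np.mean(passes)),
        "n_cohorts": n_cohorts,
        "per_cohort": passes,
        "mean_accuracy": mean_acc,
        "table": table,
    }


# ---------------------------------------------------------------------------
# geometry recovery
# ---------------------------------------------------------------------------


def geometry_recovery(n_replicates: int = 20, seed: int = 0) -> dict:
    """Sign of the orientation-consistency contrast (D_different - D_same)
    in a V1-like ROI, with and without the latent sensory component."""
    out = {}
    for label, lam in (("lam_on", None), ("lam_off", 0.0)):
        signs, amis = [], []
        for r in range(n_replicates):
            cfg = SimConfig(
                n_subjects_per_session=1, n_shared_subjects=0,
                rois=("V1",), seed=_seed(seed, 20, r),
            )
            eff = EffectParams() if lam is None else EffectParams(lam_default=0.0)
            gt = make_ground_truth(cfg, eff, seed=_seed(seed, 21, r))
            ds = simulate_subject(gt, cfg, "Ping", "S0", seed=_seed(seed, 22, r))
            tab = distance_table(_prep_set(ds), _perc_set(ds), 0.1)
            signs.append(tab.d_different > tab.d_same)
            amis.append(tab.ami)
        out[label] = {
            "positive_contrast_rate": float(np.mean(signs)),
            "mean_ami": float(np.mean(amis)),
        }
    return out


# ---------------------------------------------------------------------------
# connectivity recovery
# ---------------------------------------------------------------------------


def connectivity_recovery(
    g_grid: tuple[float, ...] = (0.0, 0.3, 0.6),
    n_cohorts: int = 10,
    n_subjects: int = 10,
    seed: int = 0,
) -> dict:
    """Informational connectivity between V1- and PFC-like ROIs as a
    function of the shared trial-gain coupling g, next to the mean-BOLD
    control connectivity computed from emitted run time series."""
    rois = ("V1", "PFC")
    ic_by_g = {g: [] for g in g_grid}
    bold_by_g = {g: [] for g in g_grid}
    for gi, g in enumerate(g_grid):
        for c in range(n_cohorts):
            ic_subj, bold_subj = [], []
            for i in range(n_subjects):
                cfg = SimConfig(
                    n_subjects_per_session=1, n_shared_subjects=0, rois=rois,
                    seed=_seed(seed, 30, gi, c, i),
                )
                eff = EffectParams(g=g)
                gt = make_ground_truth(cfg, eff, seed=_seed(seed, 31, gi, c, i))
                ds = simulate_subject(gt, cfg, "Ping", f"S{i}",
                                      seed=_seed(seed, 32, gi, c, i))
                prepared = prepare_subject(ds.patterns)
                series = {
                    r: trialwise_ami_crossval(prepared[r]["preparation"], 0.1)
                    for r in rois
                }
                ic_subj.append(informational_connectivity(series).pair("V1", "PFC"))
                runs, _ = emit_timeseries(ds)
                ts_by_roi = {
                    r: [runs[("attention", k)][r] for k in range(cfg.n_attention_runs)]
                    for r in rois
                }
                bold_subj.append(mean_bold_connectivity(ts_by_roi).pair("V1", "PFC"))
            ic_by_g[g].append(float(np.mean(ic_subj)))
            bold_by_g[g].append(float(np.mean(bold_subj)))
    return {
        "ic_median_by_g": {g: float(np.median(v)) for g, v in ic_by_g.items()},
        "bold_mean_by_g": {g: float(np.mean(v)) for g, v in bold_by_g.items()},
        "bold_sd_by_g": {g: float(np.std(v, ddof=1)) for g, v in bold_by_g.items()},
        "ic_by_g": ic_by_g,
        "bold_by_g": bold_by_g,
    }


# ---------------------------------------------------------------------------
# behavior coupling
# ---------------------------------------------------------------------------


def behavior_coupling(
    n_cohorts: int = 10,
    n_subjects: int = 20,
    seed: int = 0,
    b_rt: float | None = None,
    rt_trial_slope: float | None = None,
) -> dict:
    """AMI-behavior couplings in the Ping arm: the across-subject AMI-RT
    correlation and the strong-vs-weak modulation RT difference from
    AMI-sorted trials."""
    defaults = EffectParams()
    eff = EffectParams(
        b_rt=defaults.b_rt if b_rt is None else b_rt,
        rt_trial_slope=defaults.rt_trial_slope if rt_trial_slope is None else rt_trial_slope,
    )
    corrs, rt_diffs = [], []
    for c in range(n_cohorts):
        amis, rts, diffs = [], [], []
        for i in range(n_subjects):
            cfg = SimConfig(
                n_subjects_per_session=1, n_shared_subjects=0, rois=("V1",),
                seed=_seed(seed, 40, c, i),
            )
            gt = make_ground_truth(cfg, eff, seed=_seed(seed, 41, c, i))
            from .synthgen import _subject_level_params

            propensity, accuracy = _subject_level_params(eff, _seed(seed, 42, c), i)
            ds = simulate_subject(gt, cfg, "Ping", f"S{i}",
                                  seed=_seed(seed, 43, c, i),
                                  propensity=propensity, accuracy=accuracy)
            prep, perc = _prep_set(ds), _perc_set(ds)
            tab = distance_table(prep, perc, 0.1)
            amis.append(tab.ami)
            rts.append(float(prep.meta["rt"].mean()))
            refs = {
                o: perc.condition("orientation", o).matrix
                for o in ("leftward", "rightward")
            }
            series = trialwise_ami(prep, refs, 0.1)
            sort = sort_trials_by_ami(series, prep.meta, 0.25)
            diffs.append(sort.strong_rt - sort.weak_rt)
        ids = pd.Index([f"S{i}" for i in range(n_subjects)])
        r, _ = neural_behavior_correlation(
            pd.Series(amis, index=ids), pd.Series(rts, index=ids)
        )
        corrs.append(r)
        rt_diffs.append(float(np.mean(diffs)))
    return {
        "correlations": corrs,
        "negative_correlation_rate": float(np.mean([r < 0 for r in corrs])),
        "mean_correlation": float(np.mean(corrs)),
        "strong_minus_weak_rt": rt_diffs,
        "negative_rt_difference_rate": float(np.mean([d < 0 for d in rt_diffs])),
        "mean_rt_difference": float(np.mean(rt_diffs)),
    }
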