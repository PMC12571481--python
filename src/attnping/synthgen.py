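"""Synthetic cohort generator for a ping-probed feature-attention study.

The generator emulates a two-session fMRI design: on every attention trial a
color cue instructs the subject to attend one of two grating orientations
(leftward vs. rightward) through a blank preparation delay, after which a
compound grating appears and the cued component must be discriminated. In the
Ping session a task-irrelevant high-contrast visual impulse is flashed during
the delay. A separate perception task presents single gratings of the same
two orientations. Analyses ask whether the preparatory attentional template
is encoded in a sensory-like format (shared with perception) or a
non-sensory one, and whether the impulse reveals a latent sensory-like
component.

The ground-truth model realizes that dichotomy geometrically. Each ROI has
two orthonormal voxel axes: a *sensory* axis ``s`` carrying perceived
orientation, and an *attention* axis ``a`` carrying the preparatory
template. Preparation patterns live on ``a``; only when the ping gain
``lambda`` is nonzero (and the session is Ping) does a scaled copy of the
sensory axis leak into preparation — the latent, reactivated sensory-like
template. Stimulus selection drives both axes (target minus distractor
sensory gain). A shared trial-wise gain couples ROIs and generates
informational connectivity; a subject-level reactivation propensity couples
the attentional-modulation index to reaction times.

Both axes are constructed orthogonal to the uniform (all-ones) voxel
direction, so pattern-gain fluctuations never move the ROI-mean BOLD signal:
informational connectivity and mean-signal connectivity are dissociated by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .hrf import HRFParams, add_event
from .patterns import PatternSet

SESSIONS = ("NoPing", "Ping")
ORIENTATIONS = ("leftward", "rightward")
#: sign convention: leftward -> +1, rightward -> -1
ORIENTATION_SIGN = {"leftward": 1.0, "rightward": -1.0}


class ConfigurationError(ValueError):
    """Raised when a simulation request is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the reference design: 20 subjects per session with 14
    completing both, four ROIs of 100 voxels, six attention runs and three
    perception runs, 80% long-delay trials, TR of 2 s. 40 attention trials
    per run yields ~72 long-delay correct trials per attention condition at
    the default 75% accuracy (240 * 0.8 * 0.75 / 2).
    """

    n_subjects_per_session: int = 20
    n_shared_subjects: int = 14
    n_voxels: int = 100
    rois: tuple[str, ...] = ("V1", "EVC", "IPS", "PFC")
    n_attention_runs: int = 6
    n_perception_runs: int = 3
    trials_per_attention_run: int = 40
    trials_per_perception_run: int = 40
    p_long_delay: float = 0.8
    tr_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_subjects_per_session,
            self.n_voxels,
            self.n_attention_runs,
            self.n_perception_runs,
            self.trials_per_attention_run,
            self.trials_per_perception_run,
        )
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all design counts must be positive")
        if self.n_shared_subjects < 0 or self.n_shared_subjects > self.n_subjects_per_session:
            raise ConfigurationError(
                "n_shared_subjects must lie in [0, n_subjects_per_session]"
            )
        if not 0.0 <= self.p_long_delay <= 1.0:
            raise ConfigurationError("p_long_delay must lie in [0, 1]")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        if len(set(self.rois)) != len(self.rois):
            raise ConfigurationError("ROI names must be unique")


@dataclass(frozen=True)
class EffectParams:
    """Ground-truth effect sizes, in units of per-voxel noise SD (~1).

    beta_sens / beta_att : amplitude of the perceived-orientation signal and
        of the preparatory attention signal on their respective axes.
    lam : ping reactivation gain per ROI in [0, 1]; None selects the default
        of ``lam_default`` for V1 and EVC (where latent sensory templates
        live) and 0 elsewhere.
    gamma_target / gamma_distractor : sensory gains of the cued and uncued
        grating during stimulus selection (target > distractor).
    g : shared trial-gain coupling across ROIs (>= 0); drives informational
        connectivity.
    eta_sd : SD of the ROI-private part of the trial gain.
    ping_gain_jitter_sd : trial-to-trial SD of the ping reactivation gain;
        the jitter is what links single-trial template strength to RT.
    propensity_sd : between-subject SD of the reactivation propensity.
    b_rt : seconds of RT decrease per unit subject propensity (inter-subject
        AMI-RT coupling); rt_trial_slope is the within-subject analogue.
    accuracy_mean / accuracy_sd : subject-level Bernoulli accuracy of the
        near-threshold discrimination.
    noise_scale : overall voxel noise SD multiplier; n_noise_components and
        noise_component_scale parameterize the shared (low-rank) noise.
    """

    beta_sens: float = 1.0
    beta_att: float = 1.0
    lam: Mapping[str, float] | None = None
    lam_default: float = 0.6
    gamma_target: float = 1.0
    gamma_distractor: float = 0.3
    g: float = 0.0
    eta_sd: float = 0.15
    ping_gain_jitter_sd: float = 0.5
    propensity_sd: float = 0.25
    b_rt: float = 0.3
    rt_trial_slope: float = 0.25
    rt0: float = 0.9
    rt_noise_sd: float = 0.15
    accuracy_mean: float = 0.75
    accuracy_sd: float = 0.05
    noise_scale: float = 1.0
    n_noise_components: int = 3
    noise_component_scale: float = 0.5

    def lam_for(self, rois: tuple[str, ...]) -> dict[str, float]:
        if self.lam is not None:
            table = {r: float(self.lam.get(r, 0.0)) for r in rois}
        else:
            table = {r: (self.lam_default if r in ("V1", "EVC") else 0.0) for r in rois}
        for r, v in table.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"lambda for {r} must lie in [0, 1], got {v}")
        return table

    def validate(self) -> None:
        for name in ("beta_sens", "beta_att", "gamma_target", "gamma_distractor", "g"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ConfigurationError(f"{name} must be finite")
        if self.gamma_distractor < 0 or self.gamma_target <= self.gamma_distractor:
            raise ConfigurationError("require gamma_target > gamma_distractor >= 0")
        if self.g < 0:
            raise ConfigurationError("coupling g must be >= 0")
        if self.noise_scale <= 0:
            raise ConfigurationError("noise_scale must be positive")
        if self.n_noise_components < 0 or self.noise_component_scale < 0:
            raise ConfigurationError("noise component family must be non-negative")


@dataclass
class GroundTruth:
    """Generative parameters of one simulated brain (all ROIs)."""

    rois: tuple[str, ...]
    n_voxels: int
    mean_patterns: dict[str, np.ndarray]
    sensory_axes: dict[str, np.ndarray]
    attention_axes: dict[str, np.ndarray]
    noise_cov: dict[str, np.ndarray]
    noise_chol: dict[str, np.ndarray]
    lam: dict[str, float]
    effects: EffectParams
    seed: int

    def validate(self, atol: float = 1e-10) -> None:
        for r in self.rois:
            s, a = self.sensory_axes[r], self.attention_axes[r]
            if abs(np.linalg.norm(s) - 1) > 1e-8 or abs(np.linalg.norm(a) - 1) > 1e-8:
                raise ConfigurationError(f"axes for {r} are not unit length")
            if abs(float(s @ a)) > atol:
                raise ConfigurationError(f"axes for {r} are not orthogonal")
            np.linalg.cholesky(self.noise_cov[r])  # raises if not PD


@dataclass
class SubjectDataset:
    """All simulated data for one subject in one session."""

    subject: str
    session: str
    config: SimConfig
    ground_truth: GroundTruth
    propensity: float
    accuracy: float
    #: keyed by (roi, task, period)
    patterns: dict[tuple[str, str, str], PatternSet]
    #: one row per trial (attention and perception concatenated)
    trials: pd.DataFrame
    #: trial-wise latent variables (attention trials): z, rho, eta per ROI
    latents: pd.DataFrame
    #: optional per-run voxel time series, filled by emit_timeseries
    timeseries: dict | None = None
    events: pd.DataFrame | None = None

    def pattern_set(self, roi: str, task: str, period: str) -> PatternSet:
        return self.patterns[(roi, task, period)]


@dataclass
class Cohort:
    """A set of SubjectDatasets with a manifest of the overlap structure."""

    config: SimConfig
    effects: EffectParams
    seed: int
    manifest: dict
    datasets: dict[tuple[str, str], SubjectDataset] = field(default_factory=dict)

    def subjects(self, session: str) -> list[str]:
        return list(self.manifest["sessions"][session])

    def get(self, session: str, subject: str) -> SubjectDataset:
        return self.datasets[(session, subject)]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in key)))


def make_ground_truth(
    config: SimConfig, effects: EffectParams | None = None, seed: int = 0
) -> GroundTruth:
    """Draw one brain: per-ROI mean patterns, orthonormal signal axes and a
    diagonal-plus-low-rank noise covariance.

    Both axes are additionally orthogonal to the all-ones voxel direction so
    that axis signals carry no ROI-mean component. Deterministic given
    (config, effects, seed).
    """
    effects = effects or EffectParams()
    effects.validate()
    lam = effects.lam_for(config.rois)
    V = config.n_voxels
    means, s_axes, a_axes, covs, chols = {}, {}, {}, {}, {}
    ones = np.ones(V) / np.sqrt(V)
    for i, roi in enumerate(config.rois):
        rng = _rng(seed, 101, i)
        means[roi] = rng.normal(0.0, 0.5, size=V)
        raw = rng.standard_normal((V, 2))
        raw -= np.outer(ones, ones @ raw)  # project out the uniform direction
        q, _ = np.linalg.qr(raw)
        s_axes[roi], a_axes[roi] = q[:, 0].copy(), q[:, 1].copy()
        variances = rng.uniform(0.5, 1.5, size=V) * effects.noise_scale**2
        if np.any(variances <= 0):
            raise ConfigurationError("noise covariance request is not positive definite")
        cov = np.diag(variances)
        for _ in range(effects.n_noise_components):
            w = rng.standard_normal(V)
            w *= effects.noise_component_scale / np.linalg.norm(w)
            cov += np.outer(w, w)
        covs[roi] = cov
        try:
            chols[roi] = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - PD by construction
            raise ConfigurationError("noise covariance is not positive definite") from exc
    gt = GroundTruth(
        rois=config.rois,
        n_voxels=V,
        mean_patterns=means,
        sensory_axes=s_axes,
        attention_axes=a_axes,
        noise_cov=covs,
        noise_chol=chols,
        lam=lam,
        effects=effects,
        seed=seed,
    )
    gt.validate()
    return gt


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------


def _subject_level_params(effects: EffectParams, seed: int, subject_index: int):
    rng = _rng(seed, 202, subject_index)
    propensity = float(np.clip(rng.normal(1.0, effects.propensity_sd), 0.2, None))
    accuracy = float(np.clip(rng.normal(effects.accuracy_mean, effects.accuracy_sd), 0.55, 0.95))
    return propensity, accuracy


def _attention_trial_table(
    config: SimConfig, rng: np.random.Generator, accuracy: float
) -> pd.DataFrame:
    rows = []
    n = config.trials_per_attention_run
    half_runs = config.n_attention_runs // 2
    for run in range(config.n_attention_runs):
        orient = np.array([ORIENTATIONS[0]] * (n // 2) + [ORIENTATIONS[1]] * (n - n // 2))
        rng.shuffle(orient)
        long = rng.random(n) < config.p_long_delay
        delay_s = np.where(
            long,
            rng.choice([5.5, 7.5], size=n),
            rng.choice([1.5, 3.5], size=n),
        )
        correct = rng.random(n) < accuracy
        # color-orientation mapping reverses halfway through the runs
        first_half = run < max(half_runs, 1)
        for t in range(n):
            cue = ("red" if orient[t] == "leftward" else "green") if first_half else (
                "green" if orient[t] == "leftward" else "red"
            )
            rows.append(
                dict(
                    task="attention",
                    run=run,
                    trial_index_in_run=t,
                    orientation=orient[t],
                    delay="long" if long[t] else "short",
                    delay_seconds=float(delay_s[t]),
                    correct=bool(correct[t]),
                    cue_color=cue,
                )
            )
    return pd.DataFrame(rows)


def _perception_trial_table(config: SimConfig, rng: np.random.Generator, accuracy: float):
    rows = []
    n = config.trials_per_perception_run
    for run in range(config.n_perception_runs):
        orient = np.array([ORIENTATIONS[0]] * (n // 2) + [ORIENTATIONS[1]] * (n - n // 2))
        rng.shuffle(orient)
        correct = rng.random(n) < accuracy
        for t in range(n):
            rows.append(
                dict(
                    task="perception",
                    run=run,
                    trial_index_in_run=t,
                    orientation=orient[t],
                    delay=pd.NA,
                    delay_seconds=np.nan,
                    correct=bool(correct[t]),
                    cue_color=pd.NA,
                )
            )
    return pd.DataFrame(rows)


def simulate_subject(
    gt: GroundTruth,
    config: SimConfig,
    session: str,
    subject: str,
    seed: int,
    propensity: float | None = None,
    accuracy: float | None = None,
) -> SubjectDataset:
    """Simulate one subject-session: trial tables, latent gains and voxel
    patterns for every (ROI, task, period).

    Generative rule per attention trial t with orientation sign o:

    * preparation: ``mu + eta_t * o * beta_att * a  +  [Ping] * lam * p_s *
      rho_t * o * beta_sens * s  +  eps``
    * selection:   ``mu + eta_t * o * beta_att * a  +  o * (gamma_t -
      gamma_d) * beta_sens * s + eps``
    * perception:  ``mu + o * beta_sens * s + eps``

    with ``eta_t = 1 + g z_t + xi_{t,roi}`` (z shared across ROIs),
    ``rho_t`` the trial-wise ping jitter, ``p_s`` the subject propensity and
    ``eps ~ N(0, Sigma_roi)``.
    """
    if session not in SESSIONS:
        raise ConfigurationError(f"unknown session {session!r}; expected one of {SESSIONS}")
    if gt.n_voxels != config.n_voxels or tuple(gt.rois) != tuple(config.rois):
        raise ConfigurationError("ground truth and config disagree on ROIs/voxel counts")
    eff = gt.effects
    if propensity is None or accuracy is None:
        p0, a0 = _subject_level_params(eff, seed, 0)
        propensity = propensity if propensity is not None else p0
        accuracy = accuracy if accuracy is not None else a0
    rng = _rng(seed, 303, SESSIONS.index(session))

    att = _attention_trial_table(config, rng, accuracy)
    perc = _perception_trial_table(config, rng, accuracy)
    n_att, n_perc = len(att), len(perc)
    o_att = np.array([ORIENTATION_SIGN[o] for o in att["orientation"]])
    o_perc = np.array([ORIENTATION_SIGN[o] for o in perc["orientation"]])

    is_ping = session == "Ping"
    z = rng.standard_normal(n_att)
    rho = np.clip(1.0 + eff.ping_gain_jitter_sd * rng.standard_normal(n_att), 0.0, None)
    latents = pd.DataFrame({"z": z, "rho": rho})

    # reaction times: subject propensity sets the between-subject level; the
    # trial-wise ping jitter sets the within-subject level (Ping only)
    rt = eff.rt0 - eff.b_rt * (propensity - 1.0)
    rt = rt - (eff.rt_trial_slope * (rho - 1.0) if is_ping else 0.0)
    rt = rt + eff.rt_noise_sd * rng.standard_normal(n_att)
    att["rt"] = np.clip(rt, 0.15, None)
    perc["rt"] = np.clip(
        eff.rt0 + eff.rt_noise_sd * rng.standard_normal(n_perc), 0.15, None
    )

    patterns: dict[tuple[str, str, str], PatternSet] = {}
    for roi in config.rois:
        xi = eff.eta_sd * rng.standard_normal(n_att)
        eta = 1.0 + eff.g * z + xi
        latents[f"eta_{roi}"] = eta
        mu = gt.mean_patterns[roi]
        a_ax, s_ax = gt.attention_axes[roi], gt.sensory_axes[roi]
        lam_eff = gt.lam[roi] * propensity if is_ping else 0.0
        chol = gt.noise_chol[roi]

        def noise(n_rows: int) -> np.ndarray:
            return rng.standard_normal((n_rows, gt.n_voxels)) @ chol.T

        prep = (
            mu
            + np.outer(eta * o_att * eff.beta_att, a_ax)
            + np.outer(lam_eff * rho * o_att * eff.beta_sens, s_ax)
            + noise(n_att)
        )
        sel = (
            mu
            + np.outer(eta * o_att * eff.beta_att, a_ax)
            + np.outer(o_att * (eff.gamma_target - eff.gamma_distractor) * eff.beta_sens, s_ax)
            + noise(n_att)
        )
        pm = mu + np.outer(o_perc * eff.beta_sens, s_ax) + noise(n_perc)

        for period, mat, meta in (
            ("preparation", prep, att),
            ("selection", sel, att),
            ("perception", pm, perc),
        ):
            task = "perception" if period == "perception" else "attention"
            m = meta.copy()
            m.insert(0, "session", session)
            m.insert(0, "subject", subject)
            m["period"] = period
            patterns[(roi, task, period)] = PatternSet(
                roi=roi, matrix=mat, meta=m.reset_index(drop=True)
            )

    trials = pd.concat([att, perc], ignore_index=True)
    trials.insert(0, "session", session)
    trials.insert(0, "subject", subject)
    return SubjectDataset(
        subject=subject,
        session=session,
        config=config,
        ground_truth=gt,
        propensity=propensity,
        accuracy=accuracy,
        patterns=patterns,
        trials=trials,
        latents=latents,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimConfig,
    effects: EffectParams | None = None,
    seed: int | None = None,
    gt_factory: Callable[[int], GroundTruth] | None = None,
    sessions: tuple[str, ...] = SESSIONS,
) -> Cohort:
    """Simulate a partially overlapping two-session cohort.

    ``n_shared_subjects`` subjects appear in both sessions and reuse their
    brain (ground truth) and subject-level parameters; the remaining slots
    are filled with fresh subjects, giving ``2 * n_per_session - n_shared``
    distinct subjects in total for the default two sessions.
    """
    effects = effects or EffectParams()
    effects.validate()
    seed = config.seed if seed is None else int(seed)
    n_per, n_shared = config.n_subjects_per_session, config.n_shared_subjects
    n_total = len(sessions) * n_per - (len(sessions) - 1) * n_shared
    ids = [f"S{i:02d}" for i in range(n_total)]
    shared = ids[:n_shared]
    assignment: dict[str, list[str]] = {}
    cursor = n_shared
    for ses in sessions:
        extra = ids[cursor : cursor + (n_per - n_shared)]
        cursor += n_per - n_shared
        assignment[ses] = shared + extra

    if gt_factory is None:
        def gt_factory(idx: int) -> GroundTruth:  # one brain per distinct subject
            return make_ground_truth(config, effects, seed=(seed * 1009 + idx) % (2**31))

    manifest = {
        "seed": seed,
        "n_subjects_per_session": n_per,
        "n_shared_subjects": n_shared,
        "subjects": ids,
        "shared": shared,
        "sessions": {s: list(assignment[s]) for s in sessions},
    }
    cohort = Cohort(config=config, effects=effects, seed=seed, manifest=manifest)
    for ses in sessions:
        for sid in assignment[ses]:
            idx = ids.index(sid)
            gt = gt_factory(idx)
            propensity, accuracy = _subject_level_params(effects, seed, idx)
            child_seed = (seed * 2003 + 7 * idx) % (2**31)
            cohort.datasets[(ses, sid)] = simulate_subject(
                gt, config, ses, sid, child_seed, propensity=propensity, accuracy=accuracy
            )
    return cohort


# ---------------------------------------------------------------------------
# time-series emission
# ---------------------------------------------------------------------------

#: seconds from cue onset to grating onset is 0.5 + delay; slots keep cue
#: onsets on the TR grid and trials non-overlapping
ATTENTION_SLOT_S = 16.0
PERCEPTION_SLOT_S = 8.0
LEAD_IN_S = 4.0
TAIL_S = 24.0


def emit_timeseries(
    ds: SubjectDataset,
    hrf_params: HRFParams | None = None,
    tr_seconds: float | None = None,
    baseline: float = 100.0,
    noise_sd: float = 0.5,
    evoked_amplitude: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Render the subject's trials as per-run voxel time series.

    Each trial event contributes ``amplitude * HRF(t - onset)`` per voxel,
    where the amplitude vector is the noiseless generative pattern for that
    trial/period plus a uniform evoked component at stimulus onsets; sampled
    Gaussian noise is added on top of a flat baseline (default 100, so one
    synthetic amplitude unit is one percent signal change).

    Returns ``(runs, events)`` and stores them on the dataset. ``runs`` maps
    ``(task, run_index)`` to ``{roi: (n_samples, n_voxels) array}``.
    """
    tr = ds.config.tr_seconds if tr_seconds is None else float(tr_seconds)
    if tr <= 0:
        raise ConfigurationError("TR must be positive")
    hrf_params = hrf_params or HRFParams()
    rng = rng or _rng(ds.ground_truth.seed, 404, SESSIONS.index(ds.session))
    gt, eff = ds.ground_truth, ds.ground_truth.effects
    is_ping = ds.session == "Ping"

    runs: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    event_rows = []

    # the attention table is built run-by-run, so its positional index is
    # aligned row-for-row with ds.latents
    att = ds.trials[ds.trials["task"] == "attention"].reset_index(drop=True)
    for run in sorted(att["run"].unique()):
        rtr = att[att["run"] == run]
        dur = LEAD_IN_S + len(rtr) * ATTENTION_SLOT_S + TAIL_S
        n_samp = int(round(dur / tr))
        roi_ts = {
            roi: baseline + noise_sd * rng.standard_normal((n_samp, gt.n_voxels))
            for roi in gt.rois
        }
        for t, (lat_idx, row) in enumerate(rtr.iterrows()):
            cue_on = LEAD_IN_S + t * ATTENTION_SLOT_S
            grat_on = cue_on + 0.5 + row["delay_seconds"]
            if grat_on >= dur:
                raise ConfigurationError("event falls outside the run duration")
            o = ORIENTATION_SIGN[row["orientation"]]
            z_rho = ds.latents.iloc[lat_idx]
            for roi in gt.rois:
                eta = float(z_rho[f"eta_{roi}"])
                lam_eff = gt.lam[roi] * ds.propensity * float(z_rho["rho"]) if is_ping else 0.0
                prep_amp = (
                    gt.mean_patterns[roi]
                    + eta * o * eff.beta_att * gt.attention_axes[roi]
                    + lam_eff * o * eff.beta_sens * gt.sensory_axes[roi]
                )
                sel_amp = (
                    gt.mean_patterns[roi]
                    + eta * o * eff.beta_att * gt.attention_axes[roi]
                    + o * (eff.gamma_target - eff.gamma_distractor) * eff.beta_sens
                    * gt.sensory_axes[roi]
                    + evoked_amplitude
                )
                add_event(roi_ts[roi], cue_on, prep_amp, tr, hrf_params)
                add_event(roi_ts[roi], grat_on, sel_amp, tr, hrf_params)
            for period, onset in (("preparation", cue_on), ("selection", grat_on)):
                event_rows.append(
                    dict(
                        subject=ds.subject,
                        session=ds.session,
                        task="attention",
                        period=period,
                        run=int(run),
                        trial_index_in_run=int(row["trial_index_in_run"]),
                        orientation=row["orientation"],
                        delay=row["delay"],
                        correct=bool(row["correct"]),
                        rt=float(row["rt"]),
                        onset=float(onset),
                    )
                )
        runs[("attention", int(run))] = roi_ts

    perc = ds.trials[ds.trials["task"] == "perception"].reset_index(drop=True)
    for run in sorted(perc["run"].unique()):
        rtr = perc[perc["run"] == run].reset_index(drop=True)
        dur = LEAD_IN_S + len(rtr) * PERCEPTION_SLOT_S + TAIL_S
        n_samp = int(round(dur / tr))
        roi_ts = {
            roi: baseline + noise_sd * rng.standard_normal((n_samp, gt.n_voxels))
            for roi in gt.rois
        }
        for t, row in rtr.iterrows():
            onset = LEAD_IN_S + t * PERCEPTION_SLOT_S
            o = ORIENTATION_SIGN[row["orientation"]]
            for roi in gt.rois:
                amp = (
                    gt.mean_patterns[roi]
                    + o * eff.beta_sens * gt.sensory_axes[roi]
                    + evoked_amplitude
                )
                add_event(roi_ts[roi], onset, amp, tr, hrf_params)
            event_rows.append(
                dict(
                    subject=ds.subject,
                    session=ds.session,
                    task="perception",
                    period="perception",
                    run=int(run),
                    trial_index_in_run=int(row["trial_index_in_run"]),
                    orientation=row["orientation"],
                    delay=pd.NA,
                    correct=bool(row["correct"]),
                    rt=float(row["rt"]),
                    onset=float(onset),
                )
            )
        runs[("perception", int(run))] = roi_ts

    events = pd.DataFrame(event_rows)
    ds.timeseries = runs
    ds.events = events
    return runs, events
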