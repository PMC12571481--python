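"""Generator tests: determinism, geometry of the ground truth, trial
bookkeeping, noise structure and the latent couplings."""

import numpy as np
import pandas as pd
import pytest

from attnping import (
    EffectParams,
    SimConfig,
    emit_timeseries,
    make_ground_truth,
    simulate_cohort,
    simulate_subject,
)
from attnping.hrf import HRFParams, add_event, hrf_kernel
from attnping.synthgen import ConfigurationError


class TestGroundTruth:
    def test_deterministic_given_seed(self, tiny_config, tiny_effects):
        a = make_ground_truth(tiny_config, tiny_effects, seed=1)
        b = make_ground_truth(tiny_config, tiny_effects, seed=1)
        for roi in tiny_config.rois:
            np.testing.assert_array_equal(a.sensory_axes[roi], b.sensory_axes[roi])
            np.testing.assert_array_equal(a.noise_cov[roi], b.noise_cov[roi])

    def test_axes_orthonormal_and_mean_free(self, tiny_ground_truth):
        for roi in tiny_ground_truth.rois:
            s = tiny_ground_truth.sensory_axes[roi]
            a = tiny_ground_truth.attention_axes[roi]
            assert np.linalg.norm(s) == pytest.approx(1.0)
            assert np.linalg.norm(a) == pytest.approx(1.0)
            assert abs(s @ a) < 1e-10
            # axes carry no ROI-mean component by construction
            assert abs(s.sum()) < 1e-9 and abs(a.sum()) < 1e-9

    def test_default_lambda_layout(self):
        cfg = SimConfig(seed=0)
        gt = make_ground_truth(cfg, EffectParams(), seed=0)
        assert gt.lam["V1"] > 0 and gt.lam["EVC"] > 0
        assert gt.lam["IPS"] == 0 and gt.lam["PFC"] == 0

    def test_null_configuration(self, tiny_config):
        gt = make_ground_truth(tiny_config, EffectParams(lam_default=0.0), seed=0)
        assert all(v == 0 for v in gt.lam.values())

    def test_covariance_positive_definite(self, tiny_ground_truth):
        for roi in tiny_ground_truth.rois:
            evals = np.linalg.eigvalsh(tiny_ground_truth.noise_cov[roi])
            assert evals.min() > 0

    def test_invalid_covariance_request_rejected(self, tiny_config):
        with pytest.raises(ConfigurationError):
            make_ground_truth(tiny_config, EffectParams(noise_scale=-1.0), seed=0)

    def test_invalid_gains_rejected(self, tiny_config):
        with pytest.raises(ConfigurationError):
            make_ground_truth(
                tiny_config, EffectParams(gamma_target=0.1, gamma_distractor=0.5), seed=0
            )


class TestSimulateSubject:
    def test_unknown_session_rejected(self, tiny_ground_truth, tiny_config):
        with pytest.raises(ConfigurationError, match="session"):
            simulate_subject(tiny_ground_truth, tiny_config, "Sham", "S0", seed=1)

    def test_voxel_mismatch_rejected(self, tiny_ground_truth):
        other = SimConfig(n_voxels=10, rois=("V1", "PFC"), seed=0)
        with pytest.raises(ConfigurationError):
            simulate_subject(tiny_ground_truth, other, "Ping", "S0", seed=1)

    def test_deterministic_given_seed(self, tiny_ground_truth, tiny_config):
        a = simulate_subject(tiny_ground_truth, tiny_config, "Ping", "S0", seed=5)
        b = simulate_subject(tiny_ground_truth, tiny_config, "Ping", "S0", seed=5)
        key = ("V1", "attention", "preparation")
        np.testing.assert_array_equal(a.patterns[key].matrix, b.patterns[key].matrix)
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_noiseless_ping_patterns_match_generative_formula(self):
        """With lambda=1, vanishing noise and fixed gains, preparation
        patterns sit exactly on mu + o*(beta_att*a + beta_sens*s)."""
        cfg = SimConfig(
            n_subjects_per_session=1, n_shared_subjects=0, n_voxels=12,
            rois=("V1",), n_attention_runs=2, n_perception_runs=1,
            trials_per_attention_run=8, trials_per_perception_run=4, seed=0,
        )
        eff = EffectParams(
            lam={"V1": 1.0}, noise_scale=1e-8, n_noise_components=0,
            eta_sd=0.0, g=0.0, ping_gain_jitter_sd=0.0, propensity_sd=0.0,
        )
        gt = make_ground_truth(cfg, eff, seed=3)
        ds = simulate_subject(gt, cfg, "Ping", "S0", seed=3, propensity=1.0, accuracy=0.8)
        ps = ds.pattern_set("V1", "attention", "preparation")
        o = np.where(ps.meta["orientation"] == "leftward", 1.0, -1.0)
        expected = gt.mean_patterns["V1"] + np.outer(
            o, eff.beta_att * gt.attention_axes["V1"] + eff.beta_sens * gt.sensory_axes["V1"]
        )
        np.testing.assert_allclose(ps.matrix, expected, atol=1e-6)

    def test_expected_long_correct_trial_count(self):
        """The default design yields ~72 long-delay correct trials per
        attention condition (240 trials x 0.8 long x 0.75 correct / 2)."""
        cfg = SimConfig(seed=1)
        gt = make_ground_truth(cfg, EffectParams(), seed=1)
        counts = []
        for s in range(6):
            ds = simulate_subject(gt, cfg, "NoPing", f"S{s}", seed=50 + s,
                                  propensity=1.0, accuracy=0.75)
            t = ds.trials.query("task == 'attention' and delay == 'long' and correct")
            counts.append(t.groupby("orientation").size().mean())
        assert np.mean(counts) == pytest.approx(72, abs=6)

    def test_trial_gain_coupling_increases_with_g(self, tiny_config):
        """Inter-ROI correlation of the trial gain eta is ~0 at g=0 and
        grows monotonically over the g grid."""
        corr_at_g = []
        for g in (0.0, 0.3, 0.6):
            cors = []
            for s in range(4):
                eff = EffectParams(g=g)
                gt = make_ground_truth(tiny_config, eff, seed=11 + s)
                ds = simulate_subject(gt, tiny_config, "NoPing", "S0", seed=77 + s)
                cors.append(
                    np.corrcoef(ds.latents["eta_V1"], ds.latents["eta_PFC"])[0, 1]
                )
            corr_at_g.append(np.mean(cors))
        assert abs(corr_at_g[0]) < 0.25
        assert corr_at_g[0] < corr_at_g[1] < corr_at_g[2]

    def test_noise_covariance_recovered_at_large_n(self):
        """Sample covariance of the preparation noise converges to the
        generative covariance as the trial count grows."""
        errs = []
        for n_trials in (40, 160, 640):
            cfg = SimConfig(
                n_subjects_per_session=1, n_shared_subjects=0, n_voxels=8,
                rois=("V1",), n_attention_runs=2, n_perception_runs=1,
                trials_per_attention_run=n_trials, trials_per_perception_run=4,
                seed=0,
            )
            eff = EffectParams(beta_att=0.0, lam_default=0.0, eta_sd=0.0)
            gt = make_ground_truth(cfg, eff, seed=5)
            ds = simulate_subject(gt, cfg, "NoPing", "S0", seed=5)
            resid = ds.pattern_set("V1", "attention", "preparation").matrix
            emp = np.cov(resid, rowvar=False)
            errs.append(np.linalg.norm(emp - gt.noise_cov["V1"]))
        assert errs[2] < errs[1] < errs[0]

    def test_mean_contrast_parallel_to_attention_axis_when_lam_zero(self):
        """With no latent sensory component the empirical condition-mean
        difference aligns with the attention axis and is orthogonal to the
        sensory axis."""
        cfg = SimConfig(
            n_subjects_per_session=1, n_shared_subjects=0, n_voxels=16,
            rois=("V1",), n_attention_runs=2, n_perception_runs=1,
            trials_per_attention_run=600, trials_per_perception_run=4, seed=0,
        )
        gt = make_ground_truth(cfg, EffectParams(lam_default=0.0), seed=2)
        ds = simulate_subject(gt, cfg, "Ping", "S0", seed=2)
        ps = ds.pattern_set("V1", "attention", "preparation")
        o = ps.meta["orientation"] == "leftward"
        diff = ps.matrix[o.to_numpy()].mean(0) - ps.matrix[~o.to_numpy()].mean(0)
        diff /= np.linalg.norm(diff)
        assert abs(diff @ gt.attention_axes["V1"]) > 0.9
        assert abs(diff @ gt.sensory_axes["V1"]) < 0.2


class TestCohort:
    def test_overlap_structure(self):
        cfg = SimConfig(
            n_subjects_per_session=4, n_shared_subjects=3, n_voxels=6,
            rois=("V1",), n_attention_runs=2, n_perception_runs=1,
            trials_per_attention_run=8, trials_per_perception_run=4, seed=0,
        )
        coh = simulate_cohort(cfg, EffectParams(), seed=1)
        all_subjects = set(coh.manifest["subjects"])
        assert len(all_subjects) == 2 * 4 - 3
        both = set(coh.subjects("NoPing")) & set(coh.subjects("Ping"))
        assert both == set(coh.manifest["shared"]) and len(both) == 3

    def test_shared_subjects_reuse_subject_parameters(self):
        cfg = SimConfig(
            n_subjects_per_session=2, n_shared_subjects=1, n_voxels=6,
            rois=("V1",), n_attention_runs=2, n_perception_runs=1,
            trials_per_attention_run=8, trials_per_perception_run=4, seed=0,
        )
        coh = simulate_cohort(cfg, EffectParams(), seed=4)
        shared = coh.manifest["shared"][0]
        a, b = coh.get("NoPing", shared), coh.get("Ping", shared)
        assert a.propensity == b.propensity and a.accuracy == b.accuracy
        np.testing.assert_array_equal(
            a.ground_truth.sensory_axes["V1"], b.ground_truth.sensory_axes["V1"]
        )

    def test_disjoint_cohort(self):
        cfg = SimConfig(
            n_subjects_per_session=2, n_shared_subjects=0, n_voxels=6,
            rois=("V1",), n_attention_runs=2, n_perception_runs=1,
            trials_per_attention_run=8, trials_per_perception_run=4, seed=0,
        )
        coh = simulate_cohort(cfg, EffectParams(), seed=2)
        assert not set(coh.subjects("NoPing")) & set(coh.subjects("Ping"))

    def test_manifest_deterministic(self):
        cfg = SimConfig(
            n_subjects_per_session=2, n_shared_subjects=1, n_voxels=6,
            rois=("V1",), n_attention_runs=2, n_perception_runs=1,
            trials_per_attention_run=8, trials_per_perception_run=4, seed=0,
        )
        m1 = simulate_cohort(cfg, EffectParams(), seed=9).manifest
        m2 = simulate_cohort(cfg, EffectParams(), seed=9).manifest
        assert m1 == m2


class TestTimeseries:
    def test_single_event_matches_hrf_samples(self):
        """A unit-amplitude event on a silent baseline reproduces the HRF
        sampled at the volume grid (direct convolution oracle)."""
        tr = 2.0
        series = np.zeros(40)
        add_event(series, onset=10.0, amplitude=1.0, tr=tr)
        kern = hrf_kernel(tr)
        t = np.arange(40) * tr - 10.0
        expected = np.zeros(40)
        sup = (t >= 0) & (t <= HRFParams().duration)
        expected[sup] = np.interp(t[sup], np.arange(kern.size) * tr, kern)
        np.testing.assert_allclose(series, expected, atol=1e-12)

    def test_zero_amplitude_events_leave_noise_only(self, tiny_config):
        eff = EffectParams(beta_att=0.0, beta_sens=0.0, lam_default=0.0,
                           gamma_target=1e-12, gamma_distractor=0.0)
        gt = make_ground_truth(tiny_config, eff, seed=1)
        gt.mean_patterns = {r: np.zeros(tiny_config.n_voxels) for r in gt.rois}
        ds = simulate_subject(gt, tiny_config, "NoPing", "S0", seed=1)
        runs, _ = emit_timeseries(ds, noise_sd=0.0, evoked_amplitude=0.0, baseline=0.0)
        arr = runs[("attention", 0)]["V1"]
        np.testing.assert_allclose(arr, 0.0, atol=1e-9)

    def test_negative_tr_rejected(self, tiny_subject):
        with pytest.raises(ConfigurationError):
            emit_timeseries(tiny_subject, tr_seconds=-2.0)

    def test_event_table_aligned_with_trials(self, tiny_subject):
        runs, events = emit_timeseries(tiny_subject)
        att = events[events["task"] == "attention"]
        n_att = (tiny_subject.trials["task"] == "attention").sum()
        assert len(att) == 2 * n_att  # one preparation + one selection event each
        assert (events["onset"] >= 0).all()
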