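"""Canonical HRF, design construction, GLM fitting, contrasts, group
inference and percent signal change."""

import numpy as np
import pytest
from scipy import stats

from conftest import cover_schedule
from silentstar.glm import (
    build_design,
    canonical_hrf,
    cluster_inference,
    contrast_tmap,
    contrast_vector,
    fit_glm,
    group_ttest,
    paired_group_ttest,
    percent_signal_change,
)
from silentstar.paradigm import ParadigmConfig, ToneEvent, generate_schedule


class TestHRF:
    def test_zero_at_origin(self):
        assert canonical_hrf(0.1)[0] == 0.0

    def test_peak_near_five_seconds(self):
        dt = 0.05
        h = canonical_hrf(dt)
        assert abs(np.argmax(h) * dt - 5.0) <= dt
        assert h.max() == 1.0

    def test_single_sign_change_after_peak(self):
        h = canonical_hrf(0.05)
        post = h[np.argmax(h):]
        assert np.sum(np.diff(np.sign(post[post != 0])) != 0) == 1

    def test_matches_independent_glover_shape(self):
        """Correlates > 0.99 with nilearn's SPM-convention canonical HRF."""
        nilearn = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        dt = 0.1
        ours = canonical_hrf(dt)
        theirs = nilearn.spm_hrf(1.0, oversampling=int(1 / dt), time_length=32.0)
        m = min(len(ours), len(theirs))
        r = np.corrcoef(ours[:m], theirs[:m])[0, 1]
        assert r > 0.99

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestDesign:
    def test_row_count_after_drop(self, default_schedule):
        d = build_design(default_schedule, TR=2.5, n_vols=240, drop=10)
        assert d.matrix.shape[0] == 230
        assert "constant" in d.names
        assert d.condition_names == ["deviant", "novel", "silent"]

    def test_empty_schedule_gives_drift_and_constant_only(self):
        sched = cover_schedule(600.0)
        d = build_design(sched, TR=2.5, n_vols=240, drop=10)
        assert np.allclose(d.column("deviant"), 0.0)
        assert np.allclose(d.column("novel"), 0.0)

    def test_dct_basis_size_closed_form(self, default_schedule):
        """Drift regressors = floor(2 * retained_duration / cutoff)."""
        d = build_design(default_schedule, TR=2.5, n_vols=240, drop=10, hpf_cutoff=128.0)
        n_drift = sum(1 for n in d.names if n.startswith("drift_"))
        assert n_drift == int(np.floor(2 * 230 * 2.5 / 128.0))

    def test_highpass_protects_condition_betas(self, default_schedule):
        """A slow sinusoid (period > 256 s) shifts condition betas < 1%."""
        tr, n_vols = 2.5, 240
        d = build_design(default_schedule, TR=tr, n_vols=n_vols, drop=10)
        rng = np.random.default_rng(0)
        beta_true = rng.uniform(0.5, 1.5, d.matrix.shape[1])
        y = d.matrix @ beta_true
        t = np.arange(len(y)) * tr
        y2 = y + 0.2 * np.sin(2 * np.pi * t / 300.0)  # drift-scale sinusoid
        fit1 = fit_glm(y[None, :], d, whiten="none")
        fit2 = fit_glm(y2[None, :], d, whiten="none")
        for cond in ("deviant", "novel"):
            j = d.names.index(cond)
            assert fit2.beta[0, j] == pytest.approx(fit1.beta[0, j], rel=0.01)


class TestFit:
    def _design(self):
        sched = generate_schedule(
            ParadigmConfig(initial_silence=0.0, total_duration=300.0, n_rest_blocks=3),
            seed=1,
        )
        return build_design(sched, TR=2.5, n_vols=120, drop=0)

    def test_noiseless_exact_recovery(self):
        d = self._design()
        rng = np.random.default_rng(1)
        beta = rng.normal(size=d.matrix.shape[1])
        y = d.matrix @ beta
        fit = fit_glm(np.tile(y, (2, 1)), d, whiten="none")
        assert np.allclose(fit.beta, beta, atol=1e-8)
        assert np.allclose(fit.sigma2, 0.0, atol=1e-12)
        assert fit.df == d.matrix.shape[0] - d.matrix.shape[1]

    def test_ar1_rho_recovered(self):
        """Pooled rho estimate within 0.05 of the generating rho = 0.3
        at the study's 230 retained volumes."""
        from silentstar.acquisition import ar1_noise

        sched = generate_schedule(ParadigmConfig(), seed=2)
        d = build_design(sched, TR=2.5, n_vols=240, drop=10)
        n = d.matrix.shape[0]
        rng = np.random.default_rng(2)
        noise = ar1_noise(rng, (1000, n), 0.3, 1.0)
        y = 100.0 + noise
        fit = fit_glm(y, d, whiten="ar1")
        assert fit.ar1_rho == pytest.approx(0.3, abs=0.05)

    def test_small_system_matches_normal_equations(self):
        """6x2 system: betas and T agree with hand-solved normal equations."""
        X = np.array([[1, 0.0], [1, 1], [1, 2], [1, 3], [1, 4], [1, 5.0]])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1, 5.9])
        from silentstar.glm import DesignMatrix

        d = DesignMatrix(matrix=X, names=["constant", "slope"], TR=1.0, hpf_cutoff=128.0)
        fit = fit_glm(y[None, :], d, whiten="none")
        beta_hand = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hand
        s2 = resid @ resid / (6 - 2)
        c = np.array([0.0, 1.0])
        t_hand = (c @ beta_hand) / np.sqrt(s2 * c @ np.linalg.inv(X.T @ X) @ c)
        assert np.allclose(fit.beta[0], beta_hand)
        t = contrast_tmap(fit, c)
        assert t[0] == pytest.approx(t_hand)

    def test_rank_deficiency_names_columns(self):
        from silentstar.glm import DesignMatrix

        X = np.column_stack([np.ones(10), np.ones(10)])
        d = DesignMatrix(matrix=X, names=["constant", "dup"], TR=1.0, hpf_cutoff=128.0)
        with pytest.raises(ValueError, match="dup|constant"):
            fit_glm(np.zeros((1, 10)), d)


class TestContrasts:
    def test_negation_antisymmetry(self):
        X = np.column_stack([np.arange(10.0), np.ones(10)])
        from silentstar.glm import DesignMatrix

        d = DesignMatrix(matrix=X, names=["x", "constant"], TR=1.0, hpf_cutoff=128.0)
        rng = np.random.default_rng(3)
        y = rng.normal(size=(5, 10))
        fit = fit_glm(y, d, whiten="none")
        t_pos = contrast_tmap(fit, np.array([1.0, 0.0]))
        t_neg = contrast_tmap(fit, np.array([-1.0, 0.0]))
        assert np.allclose(t_neg, -t_pos, equal_nan=True)

    def test_zero_contrast_rejected(self):
        X = np.ones((5, 1))
        from silentstar.glm import DesignMatrix

        d = DesignMatrix(matrix=X, names=["constant"], TR=1.0, hpf_cutoff=128.0)
        fit = fit_glm(np.random.default_rng(0).normal(size=(2, 5)), d, whiten="none")
        with pytest.raises(ValueError):
            contrast_tmap(fit, np.array([0.0]))

    def test_degenerate_voxel_masked(self):
        X = np.column_stack([np.arange(10.0), np.ones(10)])
        from silentstar.glm import DesignMatrix

        d = DesignMatrix(matrix=X, names=["x", "constant"], TR=1.0, hpf_cutoff=128.0)
        y = np.zeros((1, 10))  # exact fit, sigma2 = 0
        fit = fit_glm(y, d, whiten="none")
        t = contrast_tmap(fit, np.array([1.0, 0.0]))
        assert np.isnan(t[0])

    def test_null_t_follows_student_t(self):
        """Empirical 97.5th percentile of null T within 5% of t quantile."""
        sched = generate_schedule(
            ParadigmConfig(initial_silence=0.0, total_duration=300.0, n_rest_blocks=3),
            seed=4,
        )
        d = build_design(sched, TR=2.5, n_vols=120, drop=0)
        rng = np.random.default_rng(5)
        y = rng.normal(size=(20000, d.matrix.shape[0]))
        fit = fit_glm(y, d, whiten="none")
        t = contrast_tmap(fit, "dev+nov>silent")
        q = np.quantile(t, 0.975)
        assert q == pytest.approx(stats.t.ppf(0.975, fit.df), rel=0.05)

    def test_preset_weights(self):
        sched = cover_schedule(400.0)
        d = build_design(sched, TR=2.5, n_vols=120, drop=0)
        c = contrast_vector(d, "dev+nov>silent")
        assert c[d.names.index("deviant")] == 1.0
        assert c[d.names.index("silent")] == -2.0
        assert c[d.names.index("constant")] == 0.0


class TestGroupLevel:
    def test_zero_variance_masked(self):
        maps = np.ones((5, 3, 3, 3))
        t = group_ttest(maps)
        assert np.isnan(t).all()

    def test_paired_antisymmetry(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(8, 4, 4, 4))
        b = rng.normal(size=(8, 4, 4, 4))
        assert np.allclose(paired_group_ttest(a, b), -paired_group_ttest(b, a))

    def test_group_effect_matches_noncentral_t(self):
        """d = 1, n = 12: mean T near the noncentral-t mean sqrt(n)*d."""
        rng = np.random.default_rng(7)
        n, reps = 12, 400
        tvals = []
        for _ in range(reps):
            maps = 1.0 + rng.normal(size=(n, 2, 2, 2))
            tvals.append(np.nanmean(group_ttest(maps)))
        # E[t] = delta * sqrt(n) * c_correction, delta=1
        from scipy.special import gammaln

        delta = np.sqrt(n)
        df = n - 1
        expected = delta * np.sqrt(df / 2) * np.exp(
            gammaln((df - 1) / 2) - gammaln(df / 2)
        )
        se = np.std(tvals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(tvals) - expected) < 4 * se

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            group_ttest(np.zeros((2, 2, 2, 2)))


class TestClusterInference:
    def test_zero_maps_empty_table(self):
        table = cluster_inference(np.zeros((8, 6, 6, 6)), n_perm=100, seed=0)
        assert len(table) == 0

    def test_strong_blob_detected(self):
        """A strong synthetic blob yields one significant cluster at its centre."""
        rng = np.random.default_rng(8)
        maps = rng.normal(size=(10, 12, 12, 12))
        maps[:, 4:8, 4:8, 4:8] += 5.0
        table = cluster_inference(maps, n_perm=200, seed=1)
        sig = table[table["p_corrected"] < 0.05]
        assert len(sig) == 1
        peak = sig.iloc[0]["peak_voxel"]
        assert all(4 <= p < 8 for p in peak)

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError):
            cluster_inference(np.zeros((5, 4, 4, 4)), n_perm=10)


class TestPSC:
    def _fit_with_signal(self, amp):
        sched = generate_schedule(
            ParadigmConfig(initial_silence=0.0, total_duration=320.0, n_rest_blocks=3),
            seed=9,
        )
        d = build_design(sched, TR=2.5, n_vols=120, drop=0)
        baseline = 200.0
        y = baseline + amp * baseline / 100.0 * d.column("deviant")
        fit = fit_glm(np.tile(y, (8, 1)), d, whiten="none")
        return fit

    def test_zero_beta_zero_psc(self):
        fit = self._fit_with_signal(0.0)
        roi = np.ones(8, bool)
        assert percent_signal_change(fit, roi, "deviant") == pytest.approx(0.0, abs=1e-10)

    def test_scale_invariance(self):
        fit1 = self._fit_with_signal(1.0)
        sched_amp = 1.0
        roi = np.ones(8, bool)
        psc1 = percent_signal_change(fit1, roi, "deviant")
        # doubling every signal amplitude leaves PSC unchanged
        fit2 = self._fit_with_signal(1.0)
        fit2.beta = fit2.beta * 2.0
        psc2 = percent_signal_change(fit2, roi, "deviant")
        assert psc2 == pytest.approx(psc1)

    def test_configured_modulation_recovered(self):
        """1% configured peak modulation recovers PSC within 10%."""
        fit = self._fit_with_signal(1.0)
        roi = np.ones(8, bool)
        psc = percent_signal_change(fit, roi, "deviant")
        assert psc == pytest.approx(1.0, rel=0.10)
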