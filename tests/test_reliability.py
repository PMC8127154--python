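"""ICC(3,1) maps, intra-voxel reliability and paired comparisons."""

import itertools

import numpy as np
import pytest

from silentstar.reliability import (
    icc31,
    icc31_map,
    intravoxel_icc,
    median_icc,
    network_mask,
    paired_compare,
    spearman,
    wilcoxon_exact,
)


def brute_force_icc31(table):
    """Independent oracle: explicit two-way ANOVA mean squares."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.mean()
    ss_rows = k * sum((table[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((table - grand) ** 2).sum()
    bms = ss_rows / (n - 1)
    ems = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


class TestICC31:
    def test_session_identical_subjects_distinct_gives_one(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [5.0, 5.0],
                         [7.0, 7.0], [9.0, 9.0]])
        assert icc31(vals) == pytest.approx(1.0)

    def test_zero_between_subject_variance_gives_minus_one(self):
        vals = np.array([[1.0, -1.0], [-1.0, 1.0], [1.0, -1.0],
                         [-1.0, 1.0], [1.0, -1.0], [-1.0, 1.0]])
        assert icc31(vals) == pytest.approx(-1.0)

    def test_direct_substitution(self):
        """BMS = 3, EMS = 1, k = 2 -> ICC = (3-1)/(3+1) = 0.5."""
        assert (3.0 - 1.0) / (3.0 + (2 - 1) * 1.0) == 0.5
        # and via a constructed table with those mean squares
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = rng.normal(size=(8, 2))
            m = icc31_map(table[:, :, None])
            expected = (m.bms[0] - m.ems[0]) / (m.bms[0] + m.ems[0])
            assert icc31(table) == pytest.approx(expected)

    @pytest.mark.parametrize("n,k", [(3, 2), (4, 2), (5, 3), (5, 4)])
    def test_matches_brute_force_oracle(self, n, k):
        """Agreement with the explicit ANOVA decomposition to 1e-12."""
        rng = np.random.default_rng(n * 10 + k)
        for _ in range(25):
            table = rng.normal(size=(n, k))
            assert icc31(table) == pytest.approx(
                brute_force_icc31(table), abs=1e-12
            )

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(1)
        table = rng.normal(size=(8, 3))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "session": np.tile(np.arange(3), 8),
                "y": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="session", ratings="y")
        # third row is the single-rater consistency ICC (3,1)
        ref_icc = float(ref["ICC"].iloc[2])
        assert icc31(table) == pytest.approx(ref_icc, abs=1e-9)

    def test_voxelwise_map_and_identity(self):
        rng = np.random.default_rng(2)
        maps = rng.normal(size=(6, 2, 4, 4, 4))
        out = icc31_map(maps)
        assert out.icc.shape == (4, 4, 4)
        v = (1, 2, 3)
        assert out.icc[v] == pytest.approx(icc31(maps[:, :, v[0], v[1], v[2]]))
        # invariant: ICC = (BMS - EMS)/(BMS + (k-1) EMS) wherever defined
        recon = (out.bms - out.ems) / (out.bms + (out.k - 1) * out.ems)
        assert np.allclose(out.icc[out.mask], recon[out.mask])

    def test_missing_cell_rejected(self):
        maps = np.zeros((4, 2, 3))
        maps[1, 0, 0] = np.nan
        with pytest.raises(ValueError):
            icc31_map(maps)

    def test_parameter_recovery_from_variance_components(self):
        """Mean estimated ICC over 250 simulated cohorts within the
        Monte-Carlo CI of sigma_s^2/(sigma_s^2 + sigma_e^2)."""
        rng = np.random.default_rng(3)
        s_sd, e_sd = 0.3, 0.2
        truth = s_sd**2 / (s_sd**2 + e_sd**2)
        est = []
        for _ in range(250):
            subj = rng.normal(0, s_sd, 12)
            table = subj[:, None] + rng.normal(0, e_sd, (12, 2))
            est.append(icc31(table))
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        # allow the O(1/n) small-sample bias of the ICC estimator at n=12
        assert abs(np.mean(est) - truth) < max(3 * se, 0.05)


class TestNetworkMask:
    def test_low_threshold_recovers_gm(self):
        gm = np.zeros((4, 4, 4), bool)
        gm[1:3, 1:3, 1:3] = True
        t = np.zeros((4, 4, 4))
        mask = network_mask(t, gm, t_threshold=-np.inf)
        assert np.array_equal(mask, gm)

    def test_mask_thresholds_tmap(self):
        gm = np.ones((3, 3, 3), bool)
        t = np.zeros((3, 3, 3))
        t[0, 0, 0] = 2.0
        mask = network_mask(t, gm, t_threshold=1.0)
        assert mask.sum() == 1 and mask[0, 0, 0]

    def test_median_of_constant_map(self):
        maps = np.random.default_rng(4).normal(size=(6, 2, 3, 3, 3))
        out = icc31_map(maps)
        out.icc[out.mask] = 0.7
        assert median_icc(out, np.ones((3, 3, 3), bool)) == pytest.approx(0.7)

    def test_empty_mask_rejected(self):
        maps = np.random.default_rng(5).normal(size=(6, 2, 3, 3, 3))
        with pytest.raises(ValueError):
            median_icc(icc31_map(maps), np.zeros((3, 3, 3), bool))


class TestIntraVoxel:
    def _roi(self):
        roi = np.zeros((4, 4, 4), bool)
        roi[:3, :3, :2] = True  # 18 >= 10 voxels
        return roi

    def test_identical_sessions_give_one(self):
        roi = self._roi()
        m = np.random.default_rng(6).normal(size=(4, 4, 4))
        assert intravoxel_icc(np.stack([m, m]), roi) == pytest.approx(1.0)

    def test_session_offset_invariance(self):
        """Adding a constant to one session leaves ICC_v at 1 (consistency)."""
        roi = self._roi()
        m = np.random.default_rng(7).normal(size=(4, 4, 4))
        assert intravoxel_icc(np.stack([m, m + 5.0]), roi) == pytest.approx(1.0)

    def test_common_scale_invariance(self):
        roi = self._roi()
        rng = np.random.default_rng(8)
        maps = rng.normal(size=(2, 4, 4, 4))
        a = intravoxel_icc(maps, roi)
        b = intravoxel_icc(3.5 * maps, roi)
        assert a == pytest.approx(b)

    def test_shuffled_session_near_zero(self):
        """Independent shuffles destroy spatial consistency: mean ICC_v ~ 0."""
        rng = np.random.default_rng(9)
        roi = self._roi()
        m1 = rng.normal(size=(4, 4, 4))
        vals = []
        for _ in range(300):
            m2 = m1.copy()
            flat = m2[roi]
            rng.shuffle(flat)
            m2[roi] = flat
            vals.append(intravoxel_icc(np.stack([m1, m2]), roi))
        assert abs(np.mean(vals)) < 0.05

    def test_constant_roi_undefined(self):
        roi = self._roi()
        assert np.isnan(intravoxel_icc(np.ones((2, 4, 4, 4)), roi))

    def test_small_roi_rejected(self):
        roi = np.zeros((4, 4, 4), bool)
        roi[0, 0, :3] = True
        with pytest.raises(ValueError):
            intravoxel_icc(np.zeros((2, 4, 4, 4)), roi)


class TestPairedComparisons:
    def test_all_positive_differences_exact_p(self):
        """n = 12, every difference positive: two-sided p = 2/2^12."""
        a = np.arange(1.0, 13.0) + 1.0
        b = np.arange(1.0, 13.0)
        _, p = paired_compare(a, b)
        assert p == pytest.approx(2.0 / 2**12)

    def test_enumeration_matches_brute_force(self):
        """Exact null CDF equals explicit enumeration of all sign patterns."""
        rng = np.random.default_rng(10)
        d = rng.normal(size=8)
        w_obs, p = wilcoxon_exact(d)
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(d))
        count = 0
        for signs in itertools.product([1, -1], repeat=8):
            w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
            if w_plus <= w_obs:
                count += 1
        assert p == pytest.approx(min(1.0, 2.0 * count / 2**8))

    def test_matches_scipy_exact(self):
        from scipy import stats

        rng = np.random.default_rng(11)
        for _ in range(10):
            d = rng.normal(0.4, 1.0, 12)
            _, p = wilcoxon_exact(d)
            ref = stats.wilcoxon(d, method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_identical_values_degenerate(self):
        a = np.arange(6.0)
        _, p = paired_compare(a, a)
        assert p == 1.0
        assert spearman(a, a) == pytest.approx(1.0)

    def test_reverse_ranked_spearman(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert spearman(a, a[::-1]) == pytest.approx(-1.0)

    def test_paired_t_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(12)
        a, b = rng.normal(size=12), rng.normal(size=12)
        t, p = paired_compare(a, b, method="paired_t")
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.5, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        _, p = paired_compare(a, b)
        assert 0.0 < p < 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_compare(np.zeros(5), np.zeros(6))
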