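"""Synthetic-cohort generator: sources, planted couplings, cohorts."""

import numpy as np
import pytest
from scipy import signal

from docm.bands import CANONICAL_BANDS as B
from docm.bands import mode_label
from docm.coupling import iplv, pac
from docm.docm_select import surrogate_pvalue, surrogate_swap
from docm.preprocess import bandpass, roi_representative
from docm.synth import (CouplingPlan, PairPlan, gen_cohort,
                        gen_oscillatory_source, gen_subject, gen_two_cohorts,
                        gen_voxel_rois, plant_pac, plant_phase_coupling,
                        random_plan)

RATE = 600.0


class TestOscillatorySource:
    def test_psd_peak_and_mass_in_band(self):
        x = gen_oscillatory_source(B[2], 300, RATE, 0)
        f, p = signal.welch(x, fs=RATE, nperseg=8192)
        assert B[2].f_lo <= f[np.argmax(p)] <= B[2].f_hi
        inside = (f >= B[2].f_lo) & (f <= B[2].f_hi)
        assert p[inside].sum() / p.sum() >= 0.90
        assert x.std() == pytest.approx(1.0)

    def test_determinism(self):
        a = gen_oscillatory_source(B[4], 20, RATE, 42)
        b = gen_oscillatory_source(B[4], 20, RATE, 42)
        assert np.array_equal(a, b)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            gen_oscillatory_source(B[2], 0, RATE, 0)

    def test_undersampled_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_oscillatory_source(B[7], 60, 100.0, 0)


class TestPlantPhaseCoupling:
    def test_full_strength_quarter_lag_drives_iplv_to_one(self):
        x = gen_oscillatory_source(B[2], 60, RATE, 1)
        y = plant_phase_coupling(x, B[2], np.pi / 2, 1.0, RATE, 2)
        assert iplv(x, y, B[2], RATE) >= 0.95

    def test_zero_lag_invisible_to_iplv(self):
        x = gen_oscillatory_source(B[2], 60, RATE, 3)
        with pytest.warns(UserWarning):
            y = plant_phase_coupling(x, B[2], 0.0, 1.0, RATE, 4)
        assert iplv(x, y, B[2], RATE) <= 0.05

    def test_zero_strength_matches_independent_null(self):
        """iPLV of strength-0 output is distributed like the iPLV of a
        fully independent source (Monte Carlo rank test)."""
        rng = np.random.default_rng(5)
        planted, indep = [], []
        for k in range(40):
            x = gen_oscillatory_source(B[4], 10, RATE, rng)
            y0 = plant_phase_coupling(x, B[4], np.pi / 2, 0.0, RATE, rng)
            z = gen_oscillatory_source(B[4], 10, RATE, rng)
            planted.append(iplv(x, y0, B[4], RATE))
            indep.append(iplv(x, z, B[4], RATE))
        from scipy.stats import ks_2samp
        assert ks_2samp(planted, indep).pvalue > 0.01

    def test_bad_strength_rejected(self):
        with pytest.raises(ValueError):
            plant_phase_coupling(np.random.randn(6000), B[2], 0.5, 1.5, RATE, 0)


class TestPlantPac:
    def test_high_depth_beats_surrogate_null(self):
        """depth 0.9 theta->gamma2 yields a PAC value above the 99.9th
        percentile of its single-cut surrogate distribution."""
        x = gen_oscillatory_source(B[1], 60, RATE, 6)
        y = plant_pac(x, B[1], B[7], 0.9, RATE, 7)
        obs = pac(x, y, B[1], B[7], RATE)
        rng = np.random.default_rng(8)
        surr = [pac(x, surrogate_swap(y, rng), B[1], B[7], RATE)
                for _ in range(100)]
        assert surrogate_pvalue(obs, np.asarray(surr)) < 0.01

    def test_zero_depth_null_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(60):
            x = gen_oscillatory_source(B[1], 8, RATE, rng)
            y = plant_pac(x, B[1], B[7], 0.0, RATE, rng)
            obs = pac(x, y, B[1], B[7], RATE)
            surr = [pac(x, surrogate_swap(y, rng), B[1], B[7], RATE)
                    for _ in range(39)]
            pvals.append(surrogate_pvalue(obs, np.asarray(surr)))
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_same_band_rejected(self):
        with pytest.raises(ValueError):
            plant_pac(np.random.randn(6000), B[2], B[2], 0.9, RATE, 0)

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            plant_pac(np.random.randn(6000), B[1], B[7], 1.2, RATE, 0)


class TestPlansAndSubjects:
    def test_transition_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PairPlan(0, 1, (5, 6), np.array([[0.7, 0.2], [0.5, 0.5]]))

    def test_plan_outside_rois_rejected(self):
        with pytest.raises(ValueError):
            CouplingPlan(2, [PairPlan(0, 5, (5,), np.array([[1.0]]))])

    def test_subject_determinism(self):
        plan = random_plan(4, seed=0, n_driven=1)
        a = gen_subject(plan, duration=20, seed=5)
        b = gen_subject(plan, duration=20, seed=5)
        assert np.array_equal(a.sessions[0], b.sessions[0])
        assert np.array_equal(a.sessions[1], b.sessions[1])
        assert np.array_equal(a.truth[0], b.truth[0])

    def test_sessions_differ_but_share_plan(self):
        plan = random_plan(4, seed=1, n_driven=1)
        sub = gen_subject(plan, duration=20, seed=6)
        assert not np.array_equal(sub.sessions[0], sub.sessions[1])
        assert set(np.unique(sub.truth[0])) <= set(plan.pairs[0].modes)

    def test_truth_labels_follow_plan_modes(self):
        plan = random_plan(8, seed=2)
        sub = gen_subject(plan, duration=20, seed=7)
        for p_idx, pair in enumerate(plan.pairs):
            assert set(np.unique(sub.truth[0][p_idx])) <= set(pair.modes)


class TestCohorts:
    def test_two_cohort_manifest_counts(self):
        c1, c2, manifest = gen_two_cohorts(4, 6, 3, seed=0, n_rois=4,
                                           duration=12.0)
        assert len(manifest) == 3
        assert len(c1.subjects) == 4 and len(c2.subjects) == 6
        assert all(len(s.sessions) == 2 for s in c1.subjects)
        assert all(len(s.sessions) == 1 for s in c2.subjects)
        c1_ids = {a for a, _ in manifest}
        c2_ids = {b for _, b in manifest}
        assert len(c1_ids) == 3 and len(c2_ids) == 3

    def test_overlapping_subject_shares_plan(self):
        c1, c2, manifest = gen_two_cohorts(3, 3, 2, seed=1, n_rois=4,
                                           duration=12.0)
        for a, b in manifest:
            p1, p2 = c1.subjects[a].plan, c2.subjects[b].plan
            assert [pp.modes for pp in p1.pairs] == [pp.modes for pp in p2.pairs]

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            gen_two_cohorts(2, 3, 4, seed=0)
        with pytest.raises(ValueError):
            gen_two_cohorts(2, -1, 0, seed=0)

    def test_cohort_determinism(self):
        a = gen_cohort(2, n_rois=4, duration=12, seed=9)
        b = gen_cohort(2, n_rois=4, duration=12, seed=9)
        assert np.array_equal(a.subjects[1].sessions[1], b.subjects[1].sessions[1])


class TestVoxelRois:
    def test_equal_weights_no_noise_reproduces_signal(self):
        sig = np.sin(np.linspace(0, 40, 2000)) + \
            0.1 * np.random.default_rng(0).standard_normal(2000)
        vox = gen_voxel_rois(sig, 4, noise=0.0)
        rep, _ = roi_representative(vox)
        assert np.corrcoef(rep, sig)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_dominant_voxel_gets_largest_weight(self):
        rng = np.random.default_rng(1)
        sig = bandpass(rng.standard_normal(6000), B[3], RATE)
        vox = gen_voxel_rois(sig, 4, np.array([0.97, 0.01, 0.01, 0.01]),
                             noise=0.02, seed=2)
        _, w = roi_representative(vox)
        assert np.argmax(w) == 0

    def test_single_voxel_identity(self):
        sig = np.random.default_rng(3).standard_normal(500)
        vox = gen_voxel_rois(sig, 1, noise=0.0)
        rep, _ = roi_representative(vox)
        assert np.allclose(rep, sig)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            gen_voxel_rois(np.ones(100), 3, np.zeros(3))
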