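import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermomri import synth
from thermomri.coefficients import ground_truth_value
from thermomri.synth import (
    SubjectSpec,
    add_rician_noise,
    generate_cohort,
    generate_phantom,
    simulate_dwi_signal,
    simulate_ir_se_signal,
    simulate_monoexp_signal,
    tensor_from_md_fa,
)


class TestIrSeSignal:
    def test_p_zero_removes_inversion_term(self):
        # with p=0 the recovery factor is 1 + exp(-TR/T1)
        expected = 1000 * math.exp(-12 / 80) * (1 + math.exp(-7060 / 600))
        got = simulate_ir_se_signal(1000, 0, 600, 80, ti=400, te=12, tr=7060)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_null_point_at_t1_ln2_for_long_tr(self):
        # perfect inversion, TR >> T1: signal crosses zero at TI = T1 ln 2
        t1 = 600.0
        ti_null = t1 * math.log(2)
        s = simulate_ir_se_signal(1000, 2, t1, 80, ti=ti_null, te=12, tr=1e9)
        assert abs(s) < 1e-6

    def test_printed_equation_value(self):
        # direct evaluation of the three-parameter IR equation
        s = simulate_ir_se_signal(1000, 2, 600, 80, ti=400, te=12, tr=7060)
        assert s == pytest.approx(-23.0898, abs=2e-4)

    def test_invalid_relaxation_time_rejected(self):
        with pytest.raises(ValueError):
            simulate_ir_se_signal(1000, 2, -600, 80, 400, 12, 7060)
        with pytest.raises(ValueError):
            simulate_ir_se_signal(1000, 2, 600, 0, 400, 12, 7060)


class TestMonoexpSignal:
    @pytest.mark.parametrize("s0,t2,te,expected", [
        (1000, 80, 0.0, 1000.0),
        (1000, 80, 80.0, 1000.0 / math.e),
        (500, 31.7, 50.94, 500 * math.exp(-50.94 / 31.7)),
    ])
    def test_values(self, s0, t2, te, expected):
        assert simulate_monoexp_signal(s0, t2, te) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_decay_rejected(self):
        with pytest.raises(ValueError):
            simulate_monoexp_signal(1000, 0, 10)


class TestDwiSignal:
    def test_b0_returns_s0(self):
        D = np.diag([1.5e-3, 3e-4, 3e-4])
        assert simulate_dwi_signal(750, D, 0, (1, 0, 0)) == pytest.approx(750)

    def test_isotropic_tensor(self):
        d = 7e-4
        g = np.array([1.0, 1.0, 1.0]) / math.sqrt(3)
        s = simulate_dwi_signal(1000, d * np.eye(3), 2000, g)
        assert s == pytest.approx(1000 * math.exp(-2000 * d), rel=1e-12)

    def test_diagonal_tensor_along_x(self):
        D = np.diag([1.5e-3, 3e-4, 3e-4])
        s = simulate_dwi_signal(1000, D, 2000, (1, 0, 0))
        assert s == pytest.approx(1000 * math.exp(-3.0), rel=1e-12)

    def test_asymmetric_tensor_rejected(self):
        D = np.array([[1.0, 0.1, 0], [0, 1.0, 0], [0, 0, 1.0]]) * 1e-3
        with pytest.raises(ValueError):
            simulate_dwi_signal(1000, D, 2000, (1, 0, 0))


class TestRicianNoise:
    def test_sigma_zero_returns_magnitude(self):
        assert add_rician_noise(-23.1, 0.0) == pytest.approx(23.1)

    def test_zero_signal_gives_rayleigh_mean(self):
        # |0 + n1 + i n2| is Rayleigh with mean sigma*sqrt(pi/2)
        sigma, n = 10.0, 100_000
        draws = add_rician_noise(np.zeros(n), sigma, rng=42)
        expected = sigma * math.sqrt(math.pi / 2)
        se = sigma * math.sqrt((4 - math.pi) / 2) / math.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_seed_reproducibility(self):
        a = add_rician_noise(np.full(10, 5.0), 1.0, rng=9)
        b = add_rician_noise(np.full(10, 5.0), 1.0, rng=9)
        assert np.array_equal(a, b)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(1.0, -0.1)

    @settings(deadline=None, max_examples=20)
    @given(st.floats(10.0, 1e4))
    def test_vanishing_sigma_converges_to_magnitude(self, signal):
        noisy = add_rician_noise(np.full(200, signal), 1e-9, rng=0)
        assert np.allclose(noisy, abs(signal), rtol=1e-8)


class TestGroundTruthValue:
    def test_wm_t2_at_invivo_temperature(self, table):
        got = ground_truth_value("white_matter", "T2", 36.5, table)
        assert got == pytest.approx(105.4 - 0.6 * 36.5, rel=1e-12)

    def test_zero_temperature_returns_intercept(self, table):
        got = ground_truth_value("thalamus", "MD", 0.0, table)
        assert got == pytest.approx(1.3e-4, rel=1e-12)

    def test_putamen_t1_cold(self, table):
        got = ground_truth_value("putamen", "T1", 4.0, table)
        assert got == pytest.approx(526.6, rel=1e-12)

    def test_missing_row_raises(self, table):
        with pytest.raises(KeyError):
            ground_truth_value("cerebellum", "T2", 20.0, table)


class TestTensorFromMdFa:
    @settings(deadline=None, max_examples=30)
    @given(st.floats(1e-5, 3e-3), st.floats(0.0, 0.95))
    def test_invariants_recovered(self, md, fa):
        from thermomri.dtifit import compute_fa, compute_md

        D = tensor_from_md_fa(md, fa, axis=(1, 2, 2))
        assert compute_md(D) == pytest.approx(md, rel=1e-9)
        assert compute_fa(D) == pytest.approx(fa, abs=1e-9)
        assert np.all(np.linalg.eigvalsh(D) >= -1e-18)


class TestPhantom:
    def test_zero_variation_regions_uniform(self, small_phantom):
        subject, label_vol, gt = small_phantom
        wm = label_vol.labels == synth.LABEL_CODES["white_matter"]
        assert np.ptp(gt.t1_map[wm]) == 0
        assert np.ptp(gt.t2_map[wm]) == 0

    def test_same_seed_same_phantom(self):
        spec = SubjectSpec("s", "post_mortem", 10.0, seed=3)
        lv1, gt1 = generate_phantom((16, 16, 16), subject=spec)
        lv2, gt2 = generate_phantom((16, 16, 16), subject=spec)
        assert np.array_equal(lv1.labels, lv2.labels)
        assert np.array_equal(gt1.t1_map, gt2.t1_map)
        assert np.array_equal(gt1.tensor_map, gt2.tensor_map)

    def test_wm_md_mean_matches_model_at_5p6C(self, table):
        spec = SubjectSpec("cold", "post_mortem", 5.6, seed=11)
        lv, gt = generate_phantom((32, 32, 32), subject=spec, cv=0.03)
        wm = lv.labels == synth.LABEL_CODES["white_matter"]
        md = gt.md_map()[wm]
        expected = 1.0e-4 + 4.3e-6 * 5.6
        assert md.mean() == pytest.approx(expected, rel=0.01)

    def test_boundary_voxels_partial_volume(self, small_phantom):
        _, label_vol, _ = small_phantom
        wm_pv = label_vol.pv_maps["white_matter"]
        wm = label_vol.labels == synth.LABEL_CODES["white_matter"]
        assert wm_pv[wm].max() == 1.0
        assert wm_pv[wm].min() < 1.0  # boundary voxels below 1

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom((8, 8, 8))


class TestCohort:
    def test_default_structure(self):
        subjects, df = generate_cohort(seed=5)
        assert len(subjects) == 20
        pm = [s for s in subjects if s.cohort == "post_mortem"]
        iv = [s for s in subjects if s.cohort == "in_vivo"]
        assert len(pm) == 16 and len(iv) == 4
        temps = np.array([s.brain_temperature for s in pm])
        assert temps.min() >= 5.6 and temps.max() <= 28.1
        assert all(s.brain_temperature == 36.5 for s in iv)
        assert len(df) == 20 * 7 * 5

    def test_zero_residual_recovers_generating_line(self, table):
        residual0 = {(r, p): 0.0 for r in synth.REGIONS for p in synth.PARAMETERS}
        _, df = generate_cohort(residual_sd_table=residual0, seed=2)
        from thermomri.thermal import fit_linear_model

        sub = df[(df.region == "putamen") & (df.parameter == "T1")
                 & (df.cohort == "post_mortem")]
        m = fit_linear_model(sub["mean"], sub["temperature_C"], False)
        assert m.intercept_a == pytest.approx(500.6, rel=1e-9)
        assert m.slope_b == pytest.approx(6.5, rel=1e-9)

    def test_seed_reproducible(self):
        _, a = generate_cohort(seed=8)
        _, b = generate_cohort(seed=8)
        assert a.equals(b)

    def test_subject_rows_independent_of_cohort_size(self):
        # subject i's draws depend only on the master seed and index
        subs_small, df_small = generate_cohort(n_post_mortem=4, n_in_vivo=0, seed=13)
        subs_big, df_big = generate_cohort(n_post_mortem=8, n_in_vivo=0, seed=13)
        for s_small, s_big in zip(subs_small, subs_big[:4]):
            assert s_small.brain_temperature == s_big.brain_temperature

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ValueError):
            synth.sample_post_mortem_temperatures(5, mean=1.0, sd=0.1, low=20.0, high=28.0)

    def test_in_vivo_temperature_enforced(self):
        with pytest.raises(ValueError):
            SubjectSpec("x", "in_vivo", 35.0)
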