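"""Forward model: waveform templates, phase encoding, subjects, cohorts."""

import numpy as np
import pytest

from neuroflux import dynamics as dyn
from neuroflux import synthdata as sd
from neuroflux.types import EXTRACRANIAL_VEINS, INTRACRANIAL_ARTERIES, PLANE_EXTRA, PLANE_INTRA


def brute_force_wrap(v, venc):
    """Independent aliasing oracle: shift v by 2k*venc into (-venc, venc]."""
    for k in range(-3, 4):
        w = v - 2 * k * venc
        if -venc < w <= venc:
            return w
    raise AssertionError("velocity too large for the oracle's wrap range")


class TestMakeWaveform:
    def test_zero_amplitude_arterial_is_flat(self):
        assert np.all(sd.make_waveform("arterial", 0.0, 0.3) == 0.0)

    def test_csf_waveform_is_zero_mean(self):
        w = sd.make_waveform("csf", 30.0, 0.2, 32)
        assert abs(w.sum()) < 1e-9 * np.abs(w).sum()

    def test_arterial_peak_value_and_position(self):
        # independent closed-form template evaluation at all 32 frames
        c0 = sd.baseline_fraction_for_pi(0.81, 3)
        theta = 2 * np.pi * (np.arange(32) / 32 - 4 / 32)
        expected = 400.0 * (c0 + (1 - c0) * ((1 + np.cos(theta)) / 2) ** 3)
        got = sd.make_waveform("arterial", 400.0, 4 / 32, 32)
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        assert got.max() == pytest.approx(400.0)
        assert got.argmax() == 4

    def test_unknown_kind_names_allowed_kinds(self):
        with pytest.raises(ValueError, match="arterial.*venous.*csf"):
            sd.make_waveform("lymphatic", 1.0, 0.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="n_frames"):
            sd.make_waveform("arterial", 100.0, 0.0, n_frames=4)


class TestRenderSeries:
    def test_empty_scene_is_zero_phase(self):
        series, _ = sd.render_series(sd.SceneSpec(grid=(16, 16)))
        assert np.all(series.phase == 0.0)

    def test_wrapping_matches_brute_force_oracle(self):
        scene = sd.SceneSpec(
            grid=(24, 24),
            venc_mm_s=600.0,
            vessels=[sd.VesselSpec("ICAR_i", (12, 12), 3.0, "arterial",
                                   velocity_samples=np.full(32, 700.0))],
        )
        series, gt = sd.render_series(scene)
        decoded = series.velocity()[gt.masks["ICAR_i"].mask, :]
        assert brute_force_wrap(700.0, 600.0) == pytest.approx(-500.0)
        np.testing.assert_allclose(decoded, -500.0, atol=1e-9)

    @pytest.mark.parametrize("v", [-1500.0, -601.0, -600.0, -3.0, 599.9, 600.0, 601.0, 1799.0])
    def test_wrap_decode_agrees_with_oracle(self, v):
        phase = sd.wrap_phase(np.pi * np.array(v) / 600.0)
        assert 600.0 * phase / np.pi == pytest.approx(brute_force_wrap(v, 600.0), abs=1e-9)

    def test_wrapping_is_2venc_periodic(self):
        wave = sd.make_waveform("arterial", 700.0, 4 / 32)
        vessels = [sd.VesselSpec("BA", (10, 10), 2.0, "arterial", velocity_samples=wave)]
        shifted = [sd.VesselSpec("BA", (10, 10), 2.0, "arterial",
                                 velocity_samples=wave - 2 * 600.0)]
        s1, _ = sd.render_series(sd.SceneSpec(grid=(20, 20), vessels=vessels))
        s2, _ = sd.render_series(sd.SceneSpec(grid=(20, 20), vessels=shifted))
        np.testing.assert_allclose(s1.phase, s2.phase, atol=1e-12)

    def test_disk_mask_geometry(self):
        mask = sd.disk_mask((21, 21), (10, 10), 3.0)
        rr, cc = np.mgrid[0:21, 0:21]
        np.testing.assert_array_equal(mask, (rr - 10) ** 2 + (cc - 10) ** 2 <= 9)

    def test_overlapping_vessels_rejected(self):
        scene = sd.SceneSpec(
            grid=(20, 20),
            vessels=[sd.VesselSpec("SS", (10, 10), 3.0, "venous"),
                     sd.VesselSpec("SSS", (10, 12), 3.0, "venous")],
        )
        with pytest.raises(ValueError, match="overlap"):
            sd.render_series(scene)

    def test_nonpositive_venc_rejected(self):
        with pytest.raises(ValueError, match="venc"):
            sd.SceneSpec(grid=(8, 8), venc_mm_s=0.0)

    def test_seeded_rendering_is_reproducible(self):
        scene = sd.SceneSpec(
            grid=(20, 20), noise_sd_mm_s=5.0,
            vessels=[sd.VesselSpec("BA", (10, 10), 2.0, "arterial", 200.0, 0.1)],
            seed=42,
        )
        s1, _ = sd.render_series(scene)
        s2, _ = sd.render_series(scene)
        np.testing.assert_array_equal(s1.phase, s2.phase)

    def test_forward_inverse_consistency(self):
        """Alias-free, noiseless, eddy-free: decoding recovers velocities."""
        wave = sd.make_waveform("arterial", 250.0, 4 / 32)
        scene = sd.SceneSpec(
            grid=(24, 24),
            vessels=[sd.VesselSpec("BA", (12, 12), 3.0, "arterial", velocity_samples=wave)],
        )
        series, gt = sd.render_series(scene)
        decoded = series.velocity()[gt.masks["BA"].mask, :]
        np.testing.assert_allclose(decoded, np.broadcast_to(wave, decoded.shape), atol=1e-9)


class TestSubjects:
    def test_arterial_mean_flow_hits_profile_target(self):
        truth = sd.make_subject_truth(sd.SubjectProfile(), seed=0)
        total = sum(truth.flows[PLANE_INTRA][l].mean() for l in INTRACRANIAL_ARTERIES)
        assert total == pytest.approx(659.0, rel=0.01)

    def test_full_capture_gives_unit_alpha(self):
        profile = sd.SubjectProfile(venous_capture_intra=1.0)
        truth = sd.make_subject_truth(profile, seed=0)
        corr = dyn.correct_venous(truth.qv_measured(PLANE_INTRA), truth.qa(PLANE_INTRA))
        assert corr.alpha == pytest.approx(1.0, abs=1e-12)

    def test_unilateral_jugular_waveform_is_zero(self):
        profile = sd.SubjectProfile(ijv_right_fraction=1.0)
        truth = sd.make_subject_truth(profile, seed=0)
        assert np.all(truth.flows[PLANE_EXTRA]["IJVL"].samples == 0.0)
        assert truth.flows[PLANE_EXTRA]["IJVR"].mean() < 0  # caudad drain

    def test_csf_stroke_volume_calibrated_to_profile(self):
        profile = sd.SubjectProfile(csf_noise_frac=0.0)
        truth = sd.make_subject_truth(profile, seed=0)
        sv = dyn.stroke_volume_dense(truth.csf_flow)
        assert sv == pytest.approx(profile.csf_stroke_volume_ml, rel=1e-9)

    def test_infeasible_profile_rejected(self):
        with pytest.raises(ValueError):
            sd.SubjectProfile(pi_arterial_intra=-0.5).validate()
        with pytest.raises(ValueError):
            sd.SubjectProfile(venous_capture_extra=0.0).validate()

    def test_rendered_truth_matches_waveform_truth(self, clean_subject):
        for plane, gt in clean_subject.scene_truth.items():
            for label, flow in gt.flows.items():
                np.testing.assert_allclose(
                    flow.samples, clean_subject.truth.flows[plane][label].samples,
                    rtol=1e-12,
                )


class TestCohort:
    def test_zero_sds_collapse_to_population_mean(self):
        cohort = sd.make_cohort(3, population_sds={k: 0.0 for k in sd.POPULATION_SDS})
        t = cohort.truth_table()
        assert t["pi_arterial_intra"].nunique() == 1
        assert t["pi_arterial_intra"].iloc[0] == pytest.approx(0.81)

    def test_seeded_cohort_is_bitwise_reproducible(self):
        t1 = sd.make_cohort(38, seed=11).truth_table()
        t2 = sd.make_cohort(38, seed=11).truth_table()
        assert t1.equals(t2)

    def test_sample_mean_approaches_population_mean(self):
        cohort = sd.make_cohort(200, seed=5)
        pis = [p.pi_arterial_intra for p in cohort.profiles]
        assert np.mean(pis) == pytest.approx(0.81, abs=0.03)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sd.make_cohort(1)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sds"):
            sd.make_cohort(5, population_sds={"csf_stroke_volume_ml": -0.1})
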