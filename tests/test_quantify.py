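"""Decay correction, VOI statistics, TACs, BP, volumetry, phantom resolution."""

import numpy as np
import pytest

from datspect.exceptions import ReferenceRegionError
from datspect.image_io import VolumeImage
from datspect.quantify import (VOI, TimeActivityCurve, binding_potential,
                               decay_correct, default_vois, detect_equilibrium,
                               fit_monoexponential, line_profile,
                               resolvable_rod_size, threshold_volume_curve,
                               time_activity_curves, voi_mean)
from datspect.synthetic_data import (AcquisitionSpec, KineticParams,
                                     expected_counts, make_jaszczak,
                                     simulate_acquisition, tracer_activity)


class TestDecayCorrect:
    def test_zero_time_is_identity(self):
        assert decay_correct(100.0, 0.0, 13.22) == 100.0

    def test_one_half_life_doubles(self):
        assert decay_correct(100.0, 13.22, 13.22) == pytest.approx(200.0)

    def test_inverse_restores_original(self):
        c = decay_correct(57.0, 5.0, 13.22) * 2.0 ** (-5.0 / 13.22)
        assert c == pytest.approx(57.0, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            decay_correct(-1.0, 1.0, 13.22)
        with pytest.raises(ValueError):
            decay_correct(1.0, 1.0, 0.0)


class TestVoiMean:
    def test_uniform_image(self):
        img = VolumeImage(np.full((4, 4, 4), 3.5), (1, 1, 1))
        voi = VOI("all", np.ones((4, 4, 4), bool), 1.0)
        assert voi_mean(img, voi) == 3.5

    def test_hand_set_three_voxels(self):
        data = np.zeros((3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        for i, v in enumerate([1.0, 2.0, 3.0]):
            data[i, 0, 0] = v
            mask[i, 0, 0] = True
        assert voi_mean(VolumeImage(data, (1, 1, 1)), VOI("m", mask, 1.0)) == 2.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            VOI("empty", np.zeros((3, 3, 3), bool), 1.0)

    def test_grid_mismatch_rejected(self):
        img = VolumeImage(np.zeros((4, 4, 4)), (1, 1, 1))
        voi = VOI("m", np.ones((3, 3, 3), bool), 1.0)
        with pytest.raises(ValueError):
            voi_mean(img, voi)

    def test_core_voi_partial_volume_loss_bounded(self, labels, kinetic_params,
                                                  expected_4h, acquisition_spec):
        true_s = float(kinetic_params.striatal_curve(4.0)) \
            * 2.0 ** (-4.0 / acquisition_spec.isotope_half_life_h)
        voi = default_vois(labels)["striatum"]
        measured = voi_mean(expected_4h, voi) / acquisition_spec.sensitivity
        assert abs(measured - true_s) / true_s <= 0.15

    def test_partial_volume_bias_shrinks_with_psf(self, labels, kinetic_params):
        act = tracer_activity(labels, kinetic_params, 4.0)
        true_s = float(kinetic_params.striatal_curve(4.0))
        voi = default_vois(labels)["striatum_full"]
        biases = []
        for fwhm in (1.2, 0.75, 0.3):
            acq = AcquisitionSpec(psf_fwhm_mm=fwhm, sensitivity=1.0)
            measured = voi_mean(expected_counts(act, acq), voi)
            biases.append(abs(measured - true_s) / true_s)
        assert biases[0] > biases[1] > biases[2]

    def test_unblurred_voi_mean_is_exact(self, labels, kinetic_params):
        act = tracer_activity(labels, kinetic_params, 4.0)
        voi = default_vois(labels)["striatum_full"]
        assert voi_mean(act, voi) == pytest.approx(
            float(kinetic_params.striatal_curve(4.0)), rel=1e-12)


class TestBindingPotential:
    def test_configured_healthy_ratio(self):
        assert binding_potential(7.6, 1.0).bp == pytest.approx(6.6)

    def test_equal_means_give_zero(self):
        assert binding_potential(5.0, 5.0).bp == 0.0

    @pytest.mark.parametrize("c", [0.1, 1.0, 42.0])
    def test_scale_invariant(self, c):
        assert binding_potential(7.6 * c, 1.0 * c).bp == pytest.approx(6.6)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ReferenceRegionError):
            binding_potential(5.0, 0.0)

    def test_invariant_to_common_decay_correction(self):
        s, c = 210.0, 30.0
        f = 2.0 ** (4.0 / 13.22)
        assert binding_potential(s * f, c * f).bp == pytest.approx(
            binding_potential(s, c).bp, rel=1e-12)


class TestTimeActivityCurves:
    def test_constant_images_give_flat_curve(self, labels):
        vois = {"striatum": default_vois(labels)["striatum"]}
        img = VolumeImage(np.full(labels.shape, 5.0), labels.voxel_size_mm,
                          labels.origin_mm)
        tacs = time_activity_curves([(1.0, img), (2.0, img)], vois)
        np.testing.assert_allclose(tacs["striatum"].mean_counts, 5.0)

    def test_single_time_point_rejected(self, labels, noisy_4h):
        vois = default_vois(labels)
        with pytest.raises(ValueError):
            time_activity_curves([(4.0, noisy_4h)], vois)

    def test_decay_corrected_cerebellar_curve_monotone_decreasing(
            self, labels, kinetic_params, acquisition_spec):
        frames = []
        for t in acquisition_spec.scan_midpoint_times_h:
            act = tracer_activity(labels, kinetic_params, t,
                                  acquisition_spec.isotope_half_life_h)
            frames.append((t, expected_counts(act, acquisition_spec)))
        tacs = time_activity_curves(frames, default_vois(labels),
                                    acquisition_spec.isotope_half_life_h)
        assert np.all(np.diff(tacs["cerebellum"].mean_counts) < 0)


class TestMonoexponentialFit:
    def test_exact_curve_recovered_to_machine_precision(self):
        ts = np.linspace(0.5, 7, 11)
        tac = TimeActivityCurve("cereb", ts, 80.0 * 2.0 ** (-ts / 2.5))
        a, h = fit_monoexponential(tac)
        assert h == pytest.approx(2.5, abs=1e-6)
        assert a == pytest.approx(80.0, rel=1e-6)

    def test_constant_curve_flagged_infinite(self):
        tac = TimeActivityCurve("c", [1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        _, h = fit_monoexponential(tac)
        assert np.isinf(h)

    def test_nonpositive_counts_rejected(self):
        tac = TimeActivityCurve("c", [1.0, 2.0, 3.0], [5.0, 0.0, 5.0])
        with pytest.raises(ValueError):
            fit_monoexponential(tac)


class TestDetectEquilibrium:
    def test_constant_series_detected_at_start(self):
        assert detect_equilibrium([3.0, 3.0, 3.0, 3.0]) == 0

    def test_doubling_series_never_settles(self):
        assert detect_equilibrium([1.0, 2.0, 4.0, 8.0]) is None

    def test_settling_series_detected_at_knee(self):
        assert detect_equilibrium([1.0, 2.0, 4.0, 4.1, 4.15, 4.18]) == 2

    def test_dense_default_kinetics_settle_by_four_hours(self, kinetic_params):
        # uniformly sampled every 15 min, as in the early dynamic frames
        ts = np.arange(0.25, 7.01, 0.25)
        bp = kinetic_params.striatal_curve(ts) / kinetic_params.cerebellar_curve(ts) - 1
        i = detect_equilibrium(bp, 0.10)
        assert i is not None and ts[i] <= 4.0


class TestThresholdVolume:
    def test_uniform_unblurred_ellipsoid_gives_exact_label_volume(self, labels,
                                                                  kinetic_params):
        act = tracer_activity(labels, kinetic_params, 4.0)
        seed = labels.mask("striatum_left", "striatum_right")
        curve = threshold_volume_curve(act, seed, [0.3, 0.5, 0.9, 1.0])
        # uniform hot striatum over a colder background: every threshold
        # reproduces the exact labelled volume
        expected = labels.region_volume_mm3("striatum_left", "striatum_right")
        np.testing.assert_allclose(curve.volumes_mm3, expected)

    def test_threshold_one_with_unique_maximum_gives_one_voxel(self):
        data = np.zeros((6, 6, 6))
        data[2, 2, 2] = 9.0
        data[3, 3, 3] = 5.0
        img = VolumeImage(data, (0.3, 0.3, 0.3))
        seed = data > 0
        curve = threshold_volume_curve(img, seed, [1.0])
        assert curve.volumes_mm3[0] == pytest.approx(img.voxel_volume_mm3)

    def test_volumes_non_increasing_in_threshold(self, noisy_4h, labels):
        seed = labels.mask("striatum_left", "striatum_right")
        curve = threshold_volume_curve(noisy_4h, seed,
                                       np.round(np.arange(0.1, 1.0, 0.05), 3))
        assert np.all(np.diff(curve.volumes_mm3) <= 0)

    def test_bad_thresholds_rejected(self, noisy_4h, labels):
        seed = labels.mask("striatum_left", "striatum_right")
        with pytest.raises(ValueError):
            threshold_volume_curve(noisy_4h, seed, [0.0, 0.5])
        with pytest.raises(ValueError):
            threshold_volume_curve(noisy_4h, seed, [0.5, 0.5])


class TestLineProfile:
    def test_uniform_region_is_constant(self):
        img = VolumeImage(np.full((10, 10, 10), 2.0), (0.3, 0.3, 0.3))
        prof = line_profile(img, (0.3, 0.3, 0.3), (2.4, 2.4, 2.4), 20)
        np.testing.assert_allclose(prof, 2.0)

    def test_endpoint_outside_field_rejected(self):
        img = VolumeImage(np.zeros((10, 10, 10)), (0.3, 0.3, 0.3))
        with pytest.raises(ValueError):
            line_profile(img, (0, 0, 0), (5.0, 0, 0), 10)

    def test_resolvable_rod_pair_shows_two_peaks_and_valley(self):
        image, geom = make_jaszczak()
        acq = AcquisitionSpec(psf_fwhm_mm=0.3, sensitivity=1.0)
        blurred = expected_counts(image, acq)
        sector = geom.sectors[-1]  # 1.2 mm rods
        i, j = sector.adjacent_pairs[0]
        a = np.array([*sector.centers_mm[i], np.mean(geom.z_range_mm)])
        b = np.array([*sector.centers_mm[j], np.mean(geom.z_range_mm)])
        prof = line_profile(blurred, a, b, 31)
        third = len(prof) // 3
        valley = prof[third:-third].min()
        peaks = 0.5 * (prof[:third].max() + prof[-third:].max())
        assert valley < 0.5 * peaks


class TestResolvableRods:
    def test_sharp_psf_resolves_everything(self):
        image, geom = make_jaszczak()
        acq = AcquisitionSpec(psf_fwhm_mm=0.1, sensitivity=1.0)
        smallest, scores = resolvable_rod_size(expected_counts(image, acq), geom)
        assert smallest == 0.7
        assert all(r <= 0.75 for r in scores.values())

    def test_huge_psf_resolves_nothing(self):
        image, geom = make_jaszczak()
        acq = AcquisitionSpec(psf_fwhm_mm=5.0, sensitivity=1.0)
        smallest, _ = resolvable_rod_size(expected_counts(image, acq), geom)
        assert smallest is None
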