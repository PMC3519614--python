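"""Phantom geometry, kinetics, forward model and cohort generator."""

import numpy as np
import pytest

from datspect.exceptions import ConfigError, GeometryError
from datspect.image_io import VolumeImage, resample
from datspect.synthetic_data import (AcquisitionSpec, Ellipsoid, KineticParams,
                                     PhantomSpec, PoseSpec, apply_random_pose,
                                     load_config, make_brain_labels,
                                     make_jaszczak, simulate_acquisition,
                                     simulate_cohort, tracer_activity)


class TestBrainLabels:
    def test_striatal_volume_hits_target_within_five_percent(self, labels,
                                                             phantom_spec):
        vol = labels.region_volume_mm3("striatum_left", "striatum_right")
        assert abs(vol - phantom_spec.target_striatal_volume_mm3) \
            <= 0.05 * phantom_spec.target_striatal_volume_mm3
        # ~826 voxels at 0.3 mm voxels for 22.3 mm^3
        count = labels.mask("striatum_left", "striatum_right").sum()
        assert abs(count - 22.3 / 0.027) <= 0.05 * 22.3 / 0.027

    def test_required_regions_present_and_disjoint(self, labels):
        for name in ("brain", "striatum_left", "striatum_right", "cerebellum",
                     "harderian", "eye"):
            assert labels.mask(name).any(), name
        assert not (labels.mask("striatum_left") & labels.mask("striatum_right")).any()
        assert not (labels.mask("striatum_left", "striatum_right")
                    & labels.mask("cerebellum")).any()

    def test_degenerate_ellipsoid_rejected(self):
        with pytest.raises(GeometryError):
            Ellipsoid((0, 0, 0), (1.0, 0.0, 1.0))

    def test_grid_too_small_for_brain(self):
        with pytest.raises(GeometryError):
            make_brain_labels(PhantomSpec(grid_shape=(16, 16, 16)))

    def test_geometry_is_deterministic(self, phantom_spec, labels):
        again = make_brain_labels(PhantomSpec())
        np.testing.assert_array_equal(again.data, labels.data)


class TestTracerKinetics:
    def test_cerebellar_half_value_at_half_time(self, labels, kinetic_params):
        img = tracer_activity(labels, kinetic_params, 2.5)  # no physical decay
        cereb = img.data[labels.mask("cerebellum")]
        np.testing.assert_allclose(cereb, kinetic_params.cerebellum_c0 / 2.0)

    def test_striatum_starts_at_zero(self, labels, kinetic_params):
        img = tracer_activity(labels, kinetic_params, 0.0)
        assert np.all(img.data[labels.mask("striatum_left", "striatum_right")] == 0)

    def test_striatal_peak_time_between_two_and_three_hours(self, kinetic_params):
        ts = np.linspace(0.01, 8.0, 2000)
        curve = kinetic_params.striatal_curve(ts)
        assert 2.0 <= ts[np.argmax(curve)] <= 3.0
        assert 2.0 <= kinetic_params.peak_time_h <= 3.0

    def test_striatal_curve_is_unimodal(self, kinetic_params):
        ts = np.linspace(0.01, 10.0, 3000)
        d = np.diff(kinetic_params.striatal_curve(ts))
        peak = np.argmax(d < 0)
        assert np.all(d[:peak] > 0) and np.all(d[peak:] < 0)

    def test_physical_decay_factor_applied(self, labels, kinetic_params):
        plain = tracer_activity(labels, kinetic_params, 4.0)
        decayed = tracer_activity(labels, kinetic_params, 4.0, 13.22)
        np.testing.assert_allclose(decayed.data, plain.data * 2 ** (-4.0 / 13.22))

    def test_negative_time_rejected(self, labels, kinetic_params):
        with pytest.raises(ValueError):
            tracer_activity(labels, kinetic_params, -0.1)

    def test_true_bp_matches_configuration_exactly(self, kinetic_params):
        assert kinetic_params.true_bp(4.0) == pytest.approx(6.6, abs=1e-12)

    def test_invalid_rate_constants_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(k_in_per_h=0.1, k_out_per_h=0.2)


class TestAcquisition:
    def test_default_schedule_has_eleven_increasing_midpoints(self,
                                                              acquisition_spec):
        t = np.array(acquisition_spec.scan_midpoint_times_h)
        assert len(t) == 11
        assert np.all(np.diff(t) > 0) and t[0] > 0
        np.testing.assert_allclose(t[0], 27.5 / 60)
        np.testing.assert_allclose(t[8], 147.5 / 60)
        assert tuple(t[9:]) == (4.0, 7.0)

    def test_zero_activity_gives_zero_counts(self, acquisition_spec):
        img = VolumeImage(np.zeros((8, 8, 8)), (0.3, 0.3, 0.3))
        out = simulate_acquisition(img, acquisition_spec, 0)
        assert np.all(out.data == 0)

    def test_negative_activity_rejected(self, acquisition_spec):
        img = VolumeImage(np.full((4, 4, 4), -1.0), (0.3, 0.3, 0.3))
        with pytest.raises(ValueError):
            simulate_acquisition(img, acquisition_spec, 0)

    def test_seeded_reproducibility(self, activity_4h, acquisition_spec):
        a = simulate_acquisition(activity_4h, acquisition_spec, 99)
        b = simulate_acquisition(activity_4h, acquisition_spec, 99)
        np.testing.assert_array_equal(a.data, b.data)

    def test_monte_carlo_mean_matches_blurred_expectation(self, acquisition_spec):
        from datspect.synthetic_data import expected_counts
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 500.0
        act = VolumeImage(data, (0.3, 0.3, 0.3))
        expected = expected_counts(act, acquisition_spec)
        rng = np.random.default_rng(11)
        acc = np.zeros_like(data)
        n = 1000
        for _ in range(n):
            acc += simulate_acquisition(act, acquisition_spec, rng).data
        center = acc[4, 4, 4] / n
        assert abs(center - expected.data[4, 4, 4]) < 0.05 * expected.data[4, 4, 4]

    def test_poisson_dispersion_index_near_one(self, acquisition_spec):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 200.0
        act = VolumeImage(data, (0.3, 0.3, 0.3))
        rng = np.random.default_rng(21)
        vals = np.array([simulate_acquisition(act, acquisition_spec, rng)
                         .data[2, 2, 2] for _ in range(1000)])
        dispersion = vals.var() / vals.mean()
        assert 0.9 <= dispersion <= 1.1


class TestRandomPose:
    def test_zero_bounds_give_identity(self, noisy_4h):
        posed, t = apply_random_pose(noisy_4h, PoseSpec(0.0, 0.0, 0.0), 3)
        assert t.is_identity(tol=1e-12)
        np.testing.assert_allclose(posed.data, noisy_4h.data, atol=1e-9)

    def test_round_trip_restores_image(self, expected_4h):
        posed, t = apply_random_pose(expected_4h, PoseSpec(), 4)
        back = resample(posed, t.invert())
        rms = np.sqrt(np.mean((back.data - expected_4h.data) ** 2))
        assert rms < 0.05 * expected_4h.data.max()

    def test_same_seed_same_transform(self, noisy_4h):
        _, t1 = apply_random_pose(noisy_4h, PoseSpec(), 5)
        _, t2 = apply_random_pose(noisy_4h, PoseSpec(), 5)
        np.testing.assert_array_equal(t1.matrix, t2.matrix)
        np.testing.assert_array_equal(t1.translation_mm, t2.translation_mm)

    def test_negative_bounds_rejected(self):
        with pytest.raises(ValueError):
            PoseSpec(max_rotation_deg=-1.0)


@pytest.fixture(scope="module")
def phantom():
    return make_jaszczak()


class TestJaszczak:

    def test_one_sector_per_diameter(self, phantom):
        _, geom = phantom
        assert [s.diameter_mm for s in geom.sectors] == [0.7, 0.8, 0.9, 1.0, 1.1, 1.2]
        assert all(len(s.centers_mm) >= 3 for s in geom.sectors)

    def test_center_spacing_twice_diameter(self, phantom):
        _, geom = phantom
        for sector in geom.sectors:
            c = sector.centers_mm
            for i in range(len(c)):
                d = np.linalg.norm(c - c[i], axis=1)
                nearest = d[d > 0].min()
                assert nearest == pytest.approx(2 * sector.diameter_mm, rel=0.01)

    def test_voxelized_rod_volume_matches_analytic(self, phantom):
        image, geom = phantom
        z_lo, z_hi = geom.z_range_mm
        length = z_hi - z_lo + image.voxel_size_mm[2]  # voxel-centre inclusive
        analytic = sum(len(s.centers_mm) * np.pi * (s.diameter_mm / 2) ** 2 * length
                       for s in geom.sectors)
        voxelized = image.data.sum() / geom.activity_level * image.voxel_volume_mm3
        assert voxelized == pytest.approx(analytic, rel=0.10)

    def test_sub_nyquist_diameter_warns_but_generates(self):
        with pytest.warns(UserWarning, match="sub-Nyquist"):
            image, geom = make_jaszczak(rod_diameters_mm=(0.25, 0.8))
        assert len(geom.sectors) == 2


class TestCohort:
    def test_cohort_counts_and_ground_truth(self):
        cohort = simulate_cohort(5, seed=0)
        assert len(cohort.subjects) == 5
        images = [im for s in cohort.subjects for im in (s.image_test, s.image_retest)]
        assert len(images) == 10
        for s in cohort.subjects:
            assert s.true_bp == pytest.approx(6.6, abs=1e-9)
            assert s.true_striatal_volume_mm3 > 0

    def test_zero_cv_gives_identical_parameters(self):
        cohort = simulate_cohort(3, inter_subject_cv=0.0, seed=1)
        vols = {round(s.true_striatal_volume_mm3, 6) for s in cohort.subjects}
        c0s = {s.kinetics.cerebellum_c0 for s in cohort.subjects}
        assert len(vols) == 1 and len(c0s) == 1

    def test_same_seed_identical_cohort(self):
        a = simulate_cohort(2, seed=3)
        b = simulate_cohort(2, seed=3)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.image_test.data, sb.image_test.data)
            np.testing.assert_array_equal(sa.image_retest.data, sb.image_retest.data)

    def test_retest_dose_reduced(self):
        cohort = simulate_cohort(2, inter_subject_cv=0.0, seed=2)
        for s in cohort.subjects:
            assert s.image_retest.data.sum() < s.image_test.data.sum()


class TestConfig:
    def test_round_trip_of_minimal_config(self, tmp_path):
        cfg = tmp_path / "run.toml"
        cfg.write_text(
            "[phantom]\ntarget_striatal_volume_mm3 = 17.2\n"
            "[kinetics]\ntarget_bp = 5.0\n"
            "[acquisition]\npsf_fwhm_mm = 0.6\n"
            "[cohort]\nn_subjects = 3\nseed = 9\n")
        out = load_config(cfg)
        assert out["phantom"].target_striatal_volume_mm3 == 17.2
        assert out["kinetics"].target_bp == 5.0
        assert out["acquisition"].psf_fwhm_mm == 0.6
        assert out["cohort"]["n_subjects"] == 3

    def test_unknown_keys_listed(self, tmp_path):
        cfg = tmp_path / "bad.toml"
        cfg.write_text("[kinetics]\nbogus_rate = 1.0\n")
        with pytest.raises(ConfigError, match="bogus_rate"):
            load_config(cfg)

    def test_unknown_section_rejected(self, tmp_path):
        cfg = tmp_path / "bad2.toml"
        cfg.write_text("[reconstruction]\niterations = 5\n")
        with pytest.raises(ConfigError, match="reconstruction"):
            load_config(cfg)
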