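"""Forward simulator: kinetics, Stern-Volmer forward map, renderers, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spheroxi as sx
from spheroxi.errors import ConfigurationError, PlacementError
from spheroxi.presets import viability_scene

from conftest import render_uniform_stack


def single_chamber_scene(occupancy="spheroid", core_fraction=1.0, **kwargs):
    return sx.SceneConfig(
        image_shape=(120, 120),
        pixel_size=2.0,
        chamber_centers=[(60.0, 60.0)],
        occupancy=[occupancy],
        spheroid_core_fraction=core_fraction,
        **kwargs,
    )


class TestOxygenField:
    def test_untreated_chamber_mean_at_sealing(self):
        """Initial 19.2 / plateau 13.8 kinetics put the chamber at 19.2% at t=0."""
        scene = single_chamber_scene()
        kin = sx.KineticsSpec()  # rate chosen so O2(25 min) = 13.9
        o2 = sx.simulate_oxygen_field(scene, kin, 0.0)
        mask = scene.chamber_mask(0)
        assert np.nanmean(o2[mask]) == pytest.approx(19.2, abs=1e-9)
        o2_25 = sx.simulate_oxygen_field(scene, kin, 25.0)
        assert np.nanmean(o2_25[mask]) == pytest.approx(13.9, abs=1e-9)

    def test_zero_rate_identity(self):
        scene = single_chamber_scene()
        kin = sx.KineticsSpec(rate_constant=0.0)
        o2 = sx.simulate_oxygen_field(scene, kin, 45.0)
        assert np.nanmean(o2[scene.chamber_mask(0)]) == pytest.approx(19.2)

    def test_pre_onset_delay_identity(self):
        scene = single_chamber_scene()
        kin = sx.KineticsSpec(onset_delay=20.0)
        o2 = sx.simulate_oxygen_field(scene, kin, 10.0)
        assert np.nanmean(o2[scene.chamber_mask(0)]) == pytest.approx(19.2)

    def test_empty_chambers_hold_ambient(self):
        scene = single_chamber_scene(occupancy="empty")
        o2 = sx.simulate_oxygen_field(scene, sx.KineticsSpec(), 60.0)
        assert np.all(o2[scene.chamber_mask(0)] == sx.AMBIENT_O2_PERCENT)
        assert np.isnan(o2[0, 0])  # background flag

    def test_radial_gradient_rim_to_core(self):
        """Core fraction 0.5 halves the oxygen at the spheroid center."""
        scene = single_chamber_scene(core_fraction=0.5)
        kin = sx.KineticsSpec(rate_constant=0.0)
        o2 = sx.simulate_oxygen_field(scene, kin, 0.0)
        assert o2[60, 60] == pytest.approx(0.5 * 19.2, abs=0.2)
        outside_spheroid = scene.chamber_mask(0) & ~scene.spheroid_mask(0)
        assert np.all(o2[outside_spheroid] == pytest.approx(19.2))

    def test_overlapping_chambers_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            sx.SceneConfig(
                image_shape=(100, 100),
                pixel_size=2.0,
                chamber_centers=[(50.0, 30.0), (50.0, 60.0)],
                occupancy=["empty", "empty"],
            )


class TestLifetimeFromOxygen:
    def test_unquenched_limit(self, calib):
        assert sx.lifetime_from_oxygen(0.0, calib) == pytest.approx(calib.tau0)

    def test_air_reference(self, calib):
        assert sx.lifetime_from_oxygen(20.9, calib) == pytest.approx(381.0, abs=1e-9)

    def test_drifted_reference_oracle(self, calib):
        # tau = 519.4 / (1 + 0.019089 * 13.9) = 410.48 ns, evaluated directly
        tau = calib.with_tau0(519.4).tau0 / (1 + calib.kq * 13.9)
        assert sx.lifetime_from_oxygen(13.9, calib.with_tau0(519.4)) == pytest.approx(tau)
        assert tau == pytest.approx(410.5, abs=0.1)

    def test_negative_oxygen_rejected(self, calib):
        with pytest.raises(ValueError):
            sx.lifetime_from_oxygen(-1.0, calib)

    @settings(max_examples=50, deadline=None)
    @given(
        o2=st.floats(min_value=0.0, max_value=20.9),
        kq=st.floats(min_value=1e-4, max_value=1.0),
    )
    def test_round_trip_is_identity(self, o2, kq):
        """O2 -> tau -> O2 through the quenching relation and its inverse."""
        calib = sx.CalibrationModel(kq=kq, tau_n=533.0, tau_a=100.0)
        tau = sx.lifetime_from_oxygen(o2, calib)
        assert sx.o2_from_lifetime(tau, calib.tau0, calib) == pytest.approx(
            o2, abs=1e-9
        )


class TestPhaseStackRenderer:
    def test_noise_free_stack_matches_homodyne_model(self):
        """Rendered I_k equal the cosine model exactly; demodulation is exact."""
        acq = sx.AcquisitionConfig(
            n_phase_steps=8, photon_budget=np.inf, read_noise_sd=0.0
        )
        tau = np.full((3, 3), 450.0)
        planes = sx.render_phase_stack(tau, acq)
        omega_tau = acq.omega * 450e-9
        expected = 1.0 + np.cos(acq.phase_angles - np.arctan(omega_tau)) / np.sqrt(
            1 + omega_tau**2
        )
        np.testing.assert_allclose(planes[:, 0, 0], expected, rtol=1e-12)

    def test_background_pixels_carry_stray_light_only(self):
        acq = sx.AcquisitionConfig(photon_budget=np.inf, read_noise_sd=0.0)
        tau = np.full((2, 2), np.nan)
        planes = sx.render_phase_stack(tau, acq)
        assert np.all(planes == acq.background_fraction)

    def test_poisson_lifetime_estimate_unbiased_at_1e4(self):
        """Mean pixel lifetime is within 0.5 ns of truth over 4096 replicates."""
        rng = np.random.default_rng(5)
        acq = sx.AcquisitionConfig(photon_budget=1e4, read_noise_sd=0.0)
        planes = sx.render_phase_stack(np.full((64, 64), 400.0), acq, rng)
        stack = sx.PhaseStackSeries(
            planes[None], acq.phase_angles, acq.modulation_frequency, [0.0]
        )
        tau = sx.lifetime_from_phase(sx.demodulate(stack, 0), acq.modulation_frequency)
        assert tau.tau_phase[tau.valid_mask].mean() == pytest.approx(400.0, abs=0.5)

    def test_rng_required_for_noisy_mode(self):
        acq = sx.AcquisitionConfig(photon_budget=1e3)
        with pytest.raises(ValueError, match="rng"):
            sx.render_phase_stack(np.full((2, 2), 400.0), acq)


class TestBrightfieldRenderer:
    def test_disk_area_matches_configured_diameter(self):
        scene = sx.SceneConfig(
            image_shape=(256, 256),
            pixel_size=1.0,
            chamber_centers=[(128.0, 128.0)],
            occupancy=["spheroid"],
            spheroid_diameter=114.9,
        )
        img = sx.render_brightfield(scene)
        dark = img < 0.5
        # remove the wall ring: count only the central disk
        from skimage.measure import label

        labels = label(dark)
        disk_label = labels[128, 128]
        area = (labels == disk_label).sum()
        assert area == pytest.approx(np.pi * (114.9 / 2) ** 2, rel=0.03)

    def test_empty_chamber_interior_equals_background(self):
        scene = single_chamber_scene(occupancy="empty")
        rng = np.random.default_rng(3)
        img = sx.render_brightfield(scene, rng)
        interior = scene.interior_mask(0, fraction=0.8)
        background = np.zeros_like(interior)
        background[:10, :10] = True
        assert abs(img[interior].mean() - img[background].mean()) < 0.01

    def test_single_pixel_disk(self):
        scene = sx.SceneConfig(
            image_shape=(100, 100),
            pixel_size=1.0,
            chamber_centers=[(50.0, 50.0)],
            occupancy=["spheroid"],
            spheroid_diameter=1.0,
            chamber_diameter=60.0,
        )
        img = sx.render_brightfield(scene)
        interior = scene.interior_mask(0, fraction=0.8)
        assert (img[interior] < 0.5).sum() == 1


class TestViabilityRenderer:
    def test_rounded_dead_count(self):
        """2% of 200 cells -> exactly 4 red and 196 green spots."""
        green, red, truth = sx.render_viability_pair(
            viability_scene(), 0.02, 200, np.random.default_rng(2)
        )
        assert truth["n_dead"] == 4
        assert truth["n_live"] == 196

    @pytest.mark.parametrize("dead_fraction, quiet", [(0.0, "red"), (1.0, "green")])
    def test_extreme_fractions_leave_one_channel_blank(self, dead_fraction, quiet):
        green, red, _ = sx.render_viability_pair(
            viability_scene(), dead_fraction, 30, np.random.default_rng(4), noise_sd=0.0
        )
        blank = red if quiet == "red" else green
        assert blank.max() < 0.1  # background only

    def test_overcrowded_scene_raises_placement_error(self):
        scene = sx.SceneConfig(
            image_shape=(60, 60),
            pixel_size=2.0,
            chamber_centers=[(30.0, 30.0)],
            occupancy=["spheroid"],
            spheroid_diameter=30.0,
            chamber_diameter=100.0,
        )
        with pytest.raises(PlacementError):
            sx.render_viability_pair(
                scene, 0.5, 500, np.random.default_rng(0), max_tries_per_cell=20
            )


def test_device_ground_truth_emitted(untreated_device):
    """Every simulated device carries its recovery targets."""
    gt = untreated_device.ground_truth
    assert len(gt["timepoints_min"]) == 13
    assert gt["tau_e_ns"][0] == pytest.approx(371.3)
    assert gt["tau_e_ns"][-1] == pytest.approx(364.9)
    assert gt["occupied_medium_o2_pct"][0] == pytest.approx(19.2)
    assert set(gt["chamber_mean_o2_pct"]) == {str(i) for i in range(1, 7)}
    meta = untreated_device.metadata()
    assert meta["seed"] == 7
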