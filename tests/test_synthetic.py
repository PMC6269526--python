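"""Generators: stored truth, forward models, and seeded reproducibility."""

import numpy as np
import pytest

from mpam import pam, synthetic as syn


class TestVesselPhantom:
    def test_empty_vessel_list_rejected(self):
        with pytest.raises(ValueError):
            syn.make_vessel_phantom([])

    @pytest.mark.parametrize(
        "bad",
        [
            {"so2": 1.2},
            {"so2": -0.1},
            {"diameter_um": 0.0},
            {"diameter_um": -5.0},
            {"speed_mm_s": -1.0},
        ],
    )
    def test_invalid_vessel_values_rejected(self, bad):
        spec = {"start_um": (0, 0), "end_um": (0, 100), "diameter_um": 50.0,
                "so2": 0.95, "speed_mm_s": 1.0}
        spec.update(bad)
        with pytest.raises(ValueError):
            syn.make_vessel_phantom([spec])

    def test_stored_truth_is_identity(self):
        spec = {"start_um": (100, 0), "end_um": (100, 500), "diameter_um": 50.0,
                "so2": 0.95, "speed_mm_s": 1.0, "class": "arterial"}
        phantom = syn.make_vessel_phantom([spec])
        assert len(phantom.vessels) == 1
        v = phantom.vessels[0]
        assert (v.diameter_um, v.so2, v.speed_mm_s, v.vclass) == (50.0, 0.95, 1.0, "arterial")

    def test_bifurcation_truth_conserves_flow(self):
        # oracle: evaluate F = v*pi*d^2/4 by hand for all three branches
        specs = syn.bifurcation_specs(50, 36, 30, 1.2, 0.8)
        phantom = syn.make_vessel_phantom(specs)
        hand_flow = [
            v.speed_mm_s * 1e-3 * np.pi * (v.diameter_um * 1e-6) ** 2 / 4 * 6e10
            for v in phantom.vessels
        ]
        assert abs(hand_flow[0] - (hand_flow[1] + hand_flow[2])) <= 1e-9 * hand_flow[0]
        for v, f in zip(phantom.vessels, hand_flow):
            assert v.volumetric_flow_ul_min == pytest.approx(f, rel=1e-12)

    def test_oxygen_field_must_be_nonnegative(self):
        spec = syn.straight_vessel_spec(50, 0.9, 1.0)
        with pytest.raises(ValueError):
            syn.make_vessel_phantom([spec], oxygen_field=-np.ones((4, 4)))


class TestSimulatePAM:
    def test_no_vessels_gives_zero_amplitude(self):
        phantom = syn.PhantomTruth(vessels=[], shape=(32, 32))
        scan = syn.simulate_pam_scan(phantom, noise_sd=0.0, n_repeats=12, flow_samples=64)
        assert not scan.amp[532].any() and not scan.amp[559].any()

    def test_doubling_fluence_doubles_amplitudes(self):
        phantom = syn.make_vessel_phantom(
            [syn.straight_vessel_spec(40, 0.8, 1.0, shape=(64, 64))], shape=(64, 64)
        )
        kw = dict(noise_sd=0.0, n_repeats=12, flow_samples=64, seed=3)
        s1 = syn.simulate_pam_scan(phantom, gain=1.0, **kw)
        s2 = syn.simulate_pam_scan(phantom, gain=2.0, **kw)
        for wl in (532, 559):
            np.testing.assert_allclose(s2.amp[wl], 2.0 * s1.amp[wl])

    def test_fully_oxygenated_amplitude_ratio(self, ext):
        # expected from the bundled extinction table
        fluence_ratio = 1.7
        phantom = syn.make_vessel_phantom(
            [syn.straight_vessel_spec(40, 1.0, 1.0, shape=(64, 64))], shape=(64, 64)
        )
        scan = syn.simulate_pam_scan(
            phantom, fluence_ratio=fluence_ratio, noise_sd=0.0, n_repeats=12, flow_samples=64
        )
        inside = scan.amp[559][..., 0] > 0
        ratio = scan.amp[532][inside] / scan.amp[559][inside]
        expected = fluence_ratio * ext.eps(532)[0] / ext.eps(559)[0]
        np.testing.assert_allclose(ratio, expected, rtol=1e-12)

    def test_zero_speed_stack_has_unit_correlation(self):
        phantom = syn.make_vessel_phantom(
            [syn.straight_vessel_spec(40, 0.8, 0.0, shape=(64, 64))], shape=(64, 64)
        )
        scan = syn.simulate_pam_scan(phantom, noise_sd=0.0, n_repeats=20, flow_samples=256)
        curve = pam.correlation_curve(scan.flow_stacks[1], max_lag=5)
        np.testing.assert_allclose(curve, 1.0, atol=1e-12)

    def test_seeded_scans_are_bit_identical(self):
        phantom = syn.make_vessel_phantom(
            [syn.straight_vessel_spec(40, 0.8, 1.0, shape=(48, 48))], shape=(48, 48)
        )
        kw = dict(noise_sd=0.05, seed=11, n_repeats=12, flow_samples=64)
        a = syn.simulate_pam_scan(phantom, **kw)
        b = syn.simulate_pam_scan(phantom, **kw)
        for wl in (532, 559):
            assert np.array_equal(a.amp[wl], b.amp[wl])
        assert np.array_equal(a.flow_stacks[1], b.flow_stacks[1])


class TestRatiometric:
    def test_no_oxygen_means_equal_channels(self):
        pair = syn.simulate_ratiometric_images(np.zeros((16, 16)), ksv=2.0)
        np.testing.assert_allclose(pair.blue, pair.red)

    def test_half_quench_at_po2_equal_inverse_ksv(self):
        ksv = 3.0
        pair = syn.simulate_ratiometric_images(np.full((8, 8), 1.0 / ksv), ksv=ksv)
        np.testing.assert_allclose(pair.red, pair.blue / 2.0)

    def test_background_subtraction_recovers_signal(self):
        po2 = np.linspace(0, 2, 64).reshape(8, 8)
        clean = syn.simulate_ratiometric_images(po2, ksv=1.5, backgrounds=(0.0, 0.0))
        with_bg = syn.simulate_ratiometric_images(po2, ksv=1.5, backgrounds=(0.3, 0.7))
        np.testing.assert_allclose(with_bg.blue - with_bg.blue_bg, clean.blue)
        np.testing.assert_allclose(with_bg.red - with_bg.red_bg, clean.red)

    def test_negative_ksv_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_ratiometric_images(np.zeros((4, 4)), ksv=-1.0)


class TestWoundSeries:
    def test_zero_shrink_keeps_masks_identical(self):
        masks = syn.simulate_wound_series(2.0, 0.0, days=[0, 3, 6])
        assert np.array_equal(masks[0], masks[3]) and np.array_equal(masks[0], masks[6])

    def test_halved_radius_quarters_area(self):
        # pixel-count oracle on a disc of >= 100 px radius
        masks = syn.simulate_wound_series(2.0, 0.5, days=[0, 1], pixel_size_mm=0.01)
        ratio = masks[1].sum() / masks[0].sum()
        assert ratio == pytest.approx(0.25, rel=0.01)

    def test_zero_radius_is_empty(self):
        masks = syn.simulate_wound_series(0.0, 0.1, days=[0, 5])
        assert masks[0].sum() == 0 and masks[5].sum() == 0

    def test_invalid_shrink_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_wound_series(1.0, 1.5, days=[0])
        with pytest.raises(ValueError):
            syn.simulate_wound_series(-1.0, 0.1, days=[0])


class TestPKProfile:
    def test_concentration_zero_at_time_zero(self):
        profile = syn.simulate_pk_profile()
        assert profile.conc[0] == 0.0

    def test_noiseless_peak_matches_closed_form(self):
        ka, ke = 0.6, 0.05
        t_dense = np.linspace(0, 100, 20001)
        profile = syn.simulate_pk_profile(ka, ke, 10.0, times=t_dense)
        t_star = syn.bateman_tmax(ka, ke)
        assert t_dense[np.argmax(profile.conc)] == pytest.approx(t_star, abs=0.01)

    def test_zero_scale_gives_zero_profile(self):
        profile = syn.simulate_pk_profile(scale=0.0)
        assert not profile.conc.any()

    def test_equal_rate_constants_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_pk_profile(ka=0.2, ke=0.2)

    def test_noisy_profiles_are_seed_reproducible(self):
        a = syn.simulate_pk_profile(noise_sd=2.0, seed=5)
        b = syn.simulate_pk_profile(noise_sd=2.0, seed=5)
        assert np.array_equal(a.conc, b.conc)
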