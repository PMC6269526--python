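"""Vessel segmentation, per-vessel metrics, A/V classes, OEF and MRO2."""

import numpy as np
import pandas as pd
import pytest
from conftest import perpendicular_profile_diameter, spreadsheet_oef_mro2

from mpam import pam, synthetic as syn, vessels as vq


def _tube_image(width_px=10, shape=(128, 128), angle_deg=0.0, value=1.0, pixel_size=2.0):
    spec = syn.straight_vessel_spec(
        width_px * pixel_size, 0.9, 1.0, angle_deg=angle_deg, shape=shape,
        pixel_size_um=pixel_size,
    )
    phantom = syn.make_vessel_phantom([spec], pixel_size_um=pixel_size, shape=shape)
    labels, _, _ = syn.rasterize_vessels(phantom)
    return value * (labels > 0).astype(float), labels > 0


class TestSegmentation:
    def test_blank_image_yields_empty_result(self):
        seg = vq.segment_vessels(np.zeros((64, 64)))
        assert len(seg.centerlines) == 0 and not seg.labels.any()

    def test_single_tube_yields_one_segment(self):
        img, _ = _tube_image(width_px=10)
        seg = vq.segment_vessels(img)
        assert len(seg.centerlines) == 1

    def test_crossing_tubes_split_at_junction(self):
        img1, _ = _tube_image(width_px=8, angle_deg=20)
        img2, _ = _tube_image(width_px=8, angle_deg=110)
        seg = vq.segment_vessels(np.maximum(img1, img2))
        assert len(seg.centerlines) >= 2

    def test_negative_structure_rejected(self):
        with pytest.raises(ValueError):
            vq.segment_vessels(-np.ones((8, 8)))


class TestVesselMetrics:
    def test_tube_diameter_within_tolerance(self):
        pixel = 2.0
        img, true_mask = _tube_image(width_px=10, pixel_size=pixel)
        seg = vq.segment_vessels(img)
        table = vq.vessel_metrics(seg, None, None, pixel)
        d = table["diameter_um"].iloc[0]
        assert d == pytest.approx(20.0, abs=2.0)
        # confirmed by the perpendicular-profile oracle on the true mask
        oracle_px = perpendicular_profile_diameter(true_mask, seg.centerlines[1])
        assert d == pytest.approx(oracle_px * pixel, rel=0.10)

    def test_volumetric_flow_matches_hand_conversion(self):
        """F(v=1 mm/s, d=50 um) = 1.9635e-12 m^3/s = 0.11781 uL/min."""
        hand = 1.0e-3 * np.pi * (50e-6) ** 2 / 4 * 1e9 * 60
        assert syn.flow_ul_min(1.0, 50.0) == pytest.approx(hand, rel=1e-12)
        assert syn.flow_ul_min(1.0, 50.0) == pytest.approx(0.11781, rel=1e-4)

    def test_flow_vanishes_with_diameter(self):
        assert syn.flow_ul_min(1.0, 1e-9) == pytest.approx(0.0, abs=1e-20)

    def test_missing_so2_reported_as_nan(self):
        img, _ = _tube_image(width_px=8)
        seg = vq.segment_vessels(img)
        so2 = pam.SO2Map(so2=np.full(img.shape, np.nan), valid=np.zeros(img.shape, bool))
        table = vq.vessel_metrics(seg, so2, None, 2.0)
        assert np.isnan(table["so2"].iloc[0])


def _table(rows):
    return pd.DataFrame(rows)


class TestClassifyAV:
    def test_high_so2_all_arterial(self):
        t = _table([{"vessel_id": i, "so2": 0.95, "flow_ul_min": 0.1} for i in range(3)])
        out = vq.classify_av(t)
        assert (out["class"] == "arterial").all()

    def test_threshold_tie_is_arterial(self):
        t = _table([{"vessel_id": 0, "so2": 0.75, "flow_ul_min": 0.1}])
        assert vq.classify_av(t, so2_threshold=0.75)["class"].iloc[0] == "arterial"

    def test_programmed_pair_matches_truth(self, ext):
        # nearly parallel and well separated, so the vessels do not cross
        specs = [
            syn.straight_vessel_spec(50, 0.95, 1.0, angle_deg=10, vclass="arterial"),
            syn.straight_vessel_spec(50, 0.65, 0.8, angle_deg=170, vclass="venous"),
        ]
        specs[0]["centerline_um"] = [(y - 120, x) for y, x in specs[0]["centerline_um"]]
        specs[1]["centerline_um"] = [(y + 120, x) for y, x in specs[1]["centerline_um"]]
        phantom = syn.make_vessel_phantom(specs)
        scan = syn.simulate_pam_scan(phantom, noise_sd=0.0, n_repeats=12, flow_samples=64)
        so2 = pam.unmix_so2(
            pam.project_amplitude(scan.amp[532]),
            pam.project_amplitude(scan.amp[559]),
            ext,
            noise_floor=1e-3,
        )
        seg = vq.segment_vessels(pam.structure_map(scan.amp[532]))
        table = vq.classify_av(vq.vessel_metrics(seg, so2, None, 2.0))
        assert sorted(table["class"]) == ["arterial", "venous"]

    def test_all_missing_so2_rejected(self):
        t = _table([{"vessel_id": 0, "so2": np.nan, "flow_ul_min": 0.1}])
        with pytest.raises(ValueError):
            vq.classify_av(t)


class TestOEFandMRO2:
    def _av_table(self, sa=0.95, sv=0.65, fa=0.2, fv=0.2):
        return _table(
            [
                {"vessel_id": 0, "so2": sa, "flow_ul_min": fa, "class": "arterial"},
                {"vessel_id": 1, "so2": sv, "flow_ul_min": fv, "class": "venous"},
            ]
        )

    def test_equal_saturations_give_zero_oef(self):
        s = vq.compute_oef(self._av_table(sa=0.8, sv=0.8))
        assert s.oef == 0.0

    def test_printed_formula_direct_substitution(self):
        s = vq.compute_oef(self._av_table(sa=1.0, sv=0.6))
        assert s.oef == pytest.approx(0.4, abs=1e-12)

    def test_zero_arterial_so2_rejected(self):
        with pytest.raises(ValueError):
            vq.compute_oef(self._av_table(sa=0.0, sv=0.0))

    def test_inverted_balance_flagged_not_clipped(self):
        s = vq.compute_oef(self._av_table(sa=0.6, sv=0.9))
        assert s.inverted and s.oef < 0

    def test_zero_oef_gives_zero_mro2(self):
        t = self._av_table(sa=0.8, sv=0.8)
        s = vq.compute_mro2(t, vq.compute_oef(t))
        assert s.mro2 == 0.0

    def test_unit_oef_returns_arterial_inflow(self):
        t = self._av_table(sa=0.5, sv=0.0, fa=0.37)
        s = vq.compute_mro2(t, vq.compute_oef(t))
        assert s.mro2 == pytest.approx(0.37, rel=1e-12)

    def test_matches_spreadsheet_recomputation_on_random_tables(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            n_a, n_v = rng.integers(1, 5, size=2)
            rows = [
                {"vessel_id": i, "so2": rng.uniform(0.7, 1.0),
                 "flow_ul_min": rng.uniform(0.01, 0.5), "class": "arterial"}
                for i in range(n_a)
            ] + [
                {"vessel_id": 100 + i, "so2": rng.uniform(0.3, 0.75),
                 "flow_ul_min": rng.uniform(0.01, 0.5), "class": "venous"}
                for i in range(n_v)
            ]
            table = _table(rows)
            s = vq.compute_mro2(table, vq.compute_oef(table))
            sao2, svo2, oef, mro2 = spreadsheet_oef_mro2(rows)
            assert s.sao2 == pytest.approx(sao2, rel=1e-9)
            assert s.svo2 == pytest.approx(svo2, rel=1e-9)
            assert s.oef == pytest.approx(oef, rel=1e-9)
            assert s.mro2 == pytest.approx(mro2, rel=1e-9)


class TestLongitudinalSummary:
    def _metrics(self, factor_by_day, reps=3, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for rep in range(reps):
            for day, f in factor_by_day.items():
                rows.append(
                    {
                        "replicate": rep,
                        "timepoint": day,
                        "diameter_um": 50.0 * f * (1 + jitter * rng.standard_normal()),
                        "flow_ul_min": 0.2 * f,
                        "oef": 0.3,
                        "mro2": 0.06 * f,
                    }
                )
        return pd.DataFrame(rows)

    def test_baseline_equal_everywhere_is_100_percent(self):
        out = vq.longitudinal_summary(self._metrics({0: 1.0, 7: 1.0}), baseline=0)
        np.testing.assert_allclose(out["mean"], 100.0)

    def test_single_replicate_sem_missing(self):
        out = vq.longitudinal_summary(self._metrics({0: 1.0, 7: 1.2}, reps=1), baseline=0)
        assert out["sem"].isna().all()

    def test_programmed_diameter_increase_recovered(self):
        out = vq.longitudinal_summary(
            self._metrics({0: 1.0, 7: 1.5}, reps=4, jitter=0.005, seed=2), baseline=0
        )
        row = out[(out["timepoint"] == 7) & (out["metric"] == "diameter_um")]
        assert row["mean"].iloc[0] == pytest.approx(150.0, abs=2.0)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            vq.longitudinal_summary(self._metrics({3: 1.0, 7: 1.0}), baseline=0)
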