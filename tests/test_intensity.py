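"""Intensity measurement, threshold calibration, flow gating."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synspread import (
    MultiChannelImage,
    ThresholdSet,
    calibrate_threshold,
    flow_gate_index,
    generate_flow_events,
    measure_cell_intensities,
    sample_control_patches,
)
from synspread.intensity import (
    RULE_MEAN_K_SD,
    RULE_PERCENTILE,
    CalibrationError,
)
from synspread.segment import segment_somata
from synspread.experiments import match_to_ground_truth

from conftest import make_disc_image


class TestMeasureCellIntensities:
    def test_flat_channel_gives_zero_bg_subtracted(self):
        image, labels = make_disc_image(
            centers=[(100, 100)], radii=[10], values=[500], background=500
        )
        records = measure_cell_intensities(image, labels)
        assert records["raw_mean_NFH"].iloc[0] == pytest.approx(500)
        assert records["bg_sub_NFH"].iloc[0] == pytest.approx(0.0)

    def test_background_subtraction_arithmetic(self):
        image, labels = make_disc_image(
            centers=[(100, 100)], radii=[10], values=[800], background=100
        )
        records = measure_cell_intensities(image, labels)
        assert records["raw_mean_NFH"].iloc[0] == pytest.approx(800)
        assert records["bg_sub_NFH"].iloc[0] == pytest.approx(700)

    def test_noisy_means_recover_generator_truth(self, noisy_culture):
        cfg, image, truth = noisy_culture
        # Measure over the true soma footprints so the only discrepancy
        # from the generator's recorded means is the pixel noise itself.
        from synspread import LabelMap

        lab = np.zeros(image.shape, np.int32)
        rr, cc = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
        for _, cell in truth.iterrows():
            sel = (rr - cell.row) ** 2 + (cc - cell.col) ** 2 <= cell.radius**2
            lab[sel] = int(cell.cell_id)
        records = measure_cell_intensities(image, LabelMap(labels=lab))
        assert len(records) == len(truth)
        merged = records.merge(
            truth, left_on="cell_id", right_on="cell_id", validate="1:1"
        )
        for ch in ("NFH", "eGFP", "HA"):
            deviation = np.abs(
                merged[f"raw_mean_{ch}"] - merged[f"true_{ch}"]
            ).to_numpy(float)
            tolerance = 3 * cfg.noise_sd / np.sqrt(merged["area_px2"].to_numpy(float))
            # 3·sd/sqrt(area) is a per-cell 3-sigma band: over 60 cells a
            # rare tail excursion is expected, never a gross one.
            assert (deviation < tolerance + 0.5).mean() >= 0.95
            assert np.all(deviation < 1.5 * tolerance + 0.5)

    def test_constant_offset_tracks_background(self, noiseless_culture):
        _, image, _ = noiseless_culture
        labels = segment_somata(image, "NFH")
        base = measure_cell_intensities(image, labels)
        shifted_img = MultiChannelImage(
            channels={
                ch: arr.astype(np.float64) + 57.0 for ch, arr in image.channels.items()
            },
            pixel_size=image.pixel_size,
        )
        shifted = measure_cell_intensities(shifted_img, labels)
        for ch in image.channels:
            np.testing.assert_allclose(
                shifted[f"raw_mean_{ch}"], base[f"raw_mean_{ch}"] + 57.0, atol=1e-9
            )
            assert (
                np.abs(shifted[f"bg_sub_{ch}"] - base[f"bg_sub_{ch}"]) < 1.0
            ).all()

    def test_shape_mismatch_rejected(self):
        image, labels = make_disc_image(centers=[(50, 50)], radii=[8], values=[500])
        from synspread import LabelMap

        with pytest.raises(ValueError, match="shape"):
            measure_cell_intensities(
                image, LabelMap(labels=np.zeros((10, 10), np.int32))
            )

    def test_zero_cells_gives_empty_table(self):
        from synspread import LabelMap

        image, _ = make_disc_image(centers=[], radii=[], values=[])
        records = measure_cell_intensities(
            image, LabelMap(labels=np.zeros((200, 200), np.int32))
        )
        assert records.empty

    def test_control_patches_measure_background_level(self, noiseless_culture):
        _, image, _ = noiseless_culture
        patches = sample_control_patches(image, ["eGFP"], n_patches=50, seed=1)
        assert len(patches) == 50
        # Patches land mostly on background; the median net mean is ~0.
        assert abs(patches["net_mean_eGFP"].median()) < 1.0


class TestCalibrateThreshold:
    def test_constant_controls_percentile_is_that_constant(self):
        entry = calibrate_threshold([42.0] * 30, RULE_PERCENTILE, 99.0)
        assert entry.threshold == pytest.approx(42.0)

    def test_mean_plus_k_sd_arithmetic(self):
        # Sample sd (ddof=1) of this set is exactly 10.
        values = [90.0, 110.0, 90.0, 110.0, 90.0, 110.0, 90.0, 110.0, 100.0]
        values = np.array(values)
        values = (values - values.mean()) / values.std(ddof=1) * 10.0 + 100.0
        entry = calibrate_threshold(values, RULE_MEAN_K_SD, 3.0)
        assert entry.threshold == pytest.approx(130.0)

    def test_percentile_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(0)
        controls = rng.uniform(0, 1000, 10_000)
        entry = calibrate_threshold(controls, RULE_PERCENTILE, 99.0)
        # Independent oracle: sorted linear interpolation at rank p(n-1).
        ordered = np.sort(controls)
        rank = 0.99 * (len(ordered) - 1)
        lo, hi = int(np.floor(rank)), int(np.ceil(rank))
        oracle = ordered[lo] + (rank - lo) * (ordered[hi] - ordered[lo])
        assert abs(entry.threshold - oracle) < 1.0
        assert entry.threshold == pytest.approx(990.0, abs=5.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        p1=st.floats(min_value=51.0, max_value=99.9),
        p2=st.floats(min_value=51.0, max_value=99.9),
        k1=st.floats(min_value=0.1, max_value=5.0),
        k2=st.floats(min_value=0.1, max_value=5.0),
    )
    def test_threshold_monotone_in_parameter(self, p1, p2, k1, k2):
        rng = np.random.default_rng(7)
        controls = rng.normal(100, 15, 500)
        if p1 > p2:
            p1, p2 = p2, p1
        if k1 > k2:
            k1, k2 = k2, k1
        assert (
            calibrate_threshold(controls, RULE_PERCENTILE, p1).threshold
            <= calibrate_threshold(controls, RULE_PERCENTILE, p2).threshold
        )
        assert (
            calibrate_threshold(controls, RULE_MEAN_K_SD, k1).threshold
            <= calibrate_threshold(controls, RULE_MEAN_K_SD, k2).threshold
        )

    @pytest.mark.parametrize("p", [90.0, 95.0, 99.0])
    def test_control_exceedance_bounded(self, p):
        rng = np.random.default_rng(3)
        controls = rng.normal(50, 20, 1000)
        thr = calibrate_threshold(controls, RULE_PERCENTILE, p).threshold
        exceed = float((controls > thr).mean())
        assert exceed <= (100.0 - p) / 100.0 + 1.0 / len(controls)

    def test_degenerate_inputs(self):
        with pytest.raises(CalibrationError, match="empty"):
            calibrate_threshold([], RULE_PERCENTILE, 99.0)
        with pytest.raises(CalibrationError, match="percentile"):
            calibrate_threshold([1.0, 2.0], RULE_PERCENTILE, 40.0)
        with pytest.raises(CalibrationError, match="k must"):
            calibrate_threshold([1.0, 2.0], RULE_MEAN_K_SD, 0.0)
        entry = calibrate_threshold([5.0] * 25, RULE_MEAN_K_SD, 3.0)
        assert entry.threshold == pytest.approx(5.0)
        assert entry.flagged_constant

    def test_small_control_population_flagged(self):
        entry = calibrate_threshold([1.0] * 5, RULE_PERCENTILE, 99.0)
        assert entry.low_confidence

    def test_threshold_set_json_round_trip(self, tmp_path):
        ts = ThresholdSet()
        ts.add(calibrate_threshold(np.arange(100.0), RULE_PERCENTILE, 99.0,
                                   channel="eGFP"))
        ts.add(calibrate_threshold(np.arange(50.0), RULE_MEAN_K_SD, 3.0,
                                   channel="HA"))
        path = ts.to_json(tmp_path / "thr.json")
        loaded = ThresholdSet.from_json(path)
        assert loaded["eGFP"] == ts["eGFP"]
        assert loaded["HA"] == ts["HA"]


class TestFlowGateIndex:
    def test_control_normalised_to_itself_is_one(self):
        events = generate_flow_events(seed=4)
        controls = events[~events["true_expressing"]]
        index = flow_gate_index(events, controls)
        assert index / index == pytest.approx(1.0)

    def test_empty_gate_raises(self):
        events = pd.DataFrame({"mCherry": [1.0, 2.0], "FITC": [5.0, 6.0]})
        controls = pd.DataFrame({"mCherry": [100.0, 200.0], "FITC": [1.0, 1.0]})
        with pytest.raises(CalibrationError, match="zero"):
            flow_gate_index(events, controls)

    def test_doubled_fitc_median_doubles_index(self):
        controls = generate_flow_events(seed=5, fitc_median=1000.0)
        treated = generate_flow_events(seed=6, fitc_median=2000.0)
        neg = controls[~controls["true_expressing"]]
        ratio = flow_gate_index(treated, neg) / flow_gate_index(controls, neg)
        assert ratio == pytest.approx(2.0, rel=0.05)
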