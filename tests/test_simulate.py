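"""Generator contracts: determinism, class draws, noiseless guarantees."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from synspread import (
    RegionMask,
    SyntheticConfig,
    brain_slice_layout,
    full_frame_layout,
    generate_brain_section,
    generate_culture,
    generate_fixture_suite,
    shape_for,
)
from synspread.image_io import REGION_CORTICAL, ImageIOError
from synspread.simulate import CLASS_RECIPIENT, ConfigError, PlacementError


def _class_oracle(seed: int, n: int, p_transduce: float, p_spread: float):
    """Independent re-sampling of the documented class stream.

    The class stream is the second of four children spawned from
    SeedSequence(seed); it draws n transduction uniforms then n spread
    uniforms.
    """
    class_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[1])
    u1 = class_rng.random(n)
    u2 = class_rng.random(n)
    donor = u1 < p_transduce
    recipient = ~donor & (u2 < p_spread)
    return donor.sum(), recipient.sum(), (~donor & ~recipient).sum()


def _section_class_oracle(seed, n, p_mcherry, p_transduce, p_spread):
    class_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[1])
    um = class_rng.random(n)
    u1 = class_rng.random(n)
    u2 = class_rng.random(n)
    mch = um < p_mcherry
    donor = u1 < p_transduce
    recipient = ~donor & mch & (u2 < p_spread)
    return donor, recipient, mch


class TestCultureGeneration:
    def test_identical_config_and_seed_is_bit_identical(self):
        cfg = SyntheticConfig(n_cells=40, image_shape=(360, 360), seed=5)
        img1, truth1 = generate_culture(cfg)
        img2, truth2 = generate_culture(cfg)
        for ch in img1.channels:
            np.testing.assert_array_equal(img1.channels[ch], img2.channels[ch])
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_degenerate_probabilities(self):
        cfg = SyntheticConfig(
            n_cells=30, image_shape=(360, 360), p_transduce=1.0, seed=1
        )
        _, truth = generate_culture(cfg)
        assert set(truth["true_class"]) == {"DONOR"}

        cfg0 = cfg.replace(p_transduce=0.0, p_spread=0.0, noise_sd=0.0)
        img, truth = generate_culture(cfg0)
        assert set(truth["true_class"]) == {"UNTRANSDUCED"}
        # Reporter channels hold nothing but background.
        assert img.channels["eGFP"].min() == img.channels["eGFP"].max() == 100
        assert img.channels["HA"].min() == img.channels["HA"].max() == 100

    def test_class_counts_match_resampling_oracle(self):
        cfg = SyntheticConfig(
            n_cells=100, image_shape=(480, 480), p_transduce=0.6, p_spread=0.2, seed=42
        )
        _, truth = generate_culture(cfg)
        counts = truth["true_class"].value_counts()
        d, r, u = _class_oracle(42, 100, 0.6, 0.2)
        assert counts.get("DONOR", 0) == d
        assert counts.get("RECIPIENT", 0) == r
        assert counts.get("UNTRANSDUCED", 0) == u

    def test_recipient_count_monotone_in_p_spread_under_crn(self):
        cfg = SyntheticConfig(n_cells=200, image_shape=(640, 640), seed=9)
        previous = -1
        for p in (0.0, 0.05, 0.2, 0.5, 1.0):
            _, truth = generate_culture(cfg.replace(p_spread=p))
            count = int((truth["true_class"] == CLASS_RECIPIENT).sum())
            assert count >= previous
            previous = count

    def test_class_frequency_converges_to_p_transduce(self):
        # Small somata keep 1000-cell frames cheap; only classes matter here.
        n, p = 1000, 0.6
        shape = shape_for(n, min_separation=13.0, soma_radius=(4.0, 0.5))
        fractions = []
        for seed in range(50):
            cfg = SyntheticConfig(
                n_cells=n, image_shape=shape, soma_radius=(4.0, 0.5),
                min_separation=13.0, noise_sd=0.0, seed=seed,
            )
            _, truth = generate_culture(cfg)
            fractions.append((truth["true_class"] == "DONOR").mean())
        se = np.sqrt(p * (1 - p) / (n * 50))
        assert abs(np.mean(fractions) - p) < 3 * se

    def test_noiseless_reporter_guarantees(self, noiseless_culture):
        cfg, image, truth = noiseless_culture
        egfp = image.channels["eGFP"].astype(float)
        ha = image.channels["HA"].astype(float)
        rr, cc = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
        for _, cell in truth.iterrows():
            soma = (rr - cell.row) ** 2 + (cc - cell.col) ** 2 <= cell.radius**2
            if cell.true_class == "DONOR":
                assert (egfp[soma] > cfg.background_level).all()
                assert (ha[soma] > cfg.background_level).all()
            elif cell.true_class == "RECIPIENT":
                np.testing.assert_array_equal(egfp[soma], cfg.background_level)
                assert (ha[soma] > cfg.background_level).all()
            else:
                np.testing.assert_array_equal(egfp[soma], cfg.background_level)
                np.testing.assert_array_equal(ha[soma], cfg.background_level)

    def test_placement_failure_names_min_separation(self):
        cfg = SyntheticConfig(
            n_cells=50, image_shape=(360, 360), min_separation=45.0, seed=0
        )
        with pytest.raises((PlacementError, ConfigError), match="min_separation"):
            generate_culture(cfg)

    @pytest.mark.parametrize(
        "overrides",
        [
            {"p_transduce": 1.5},
            {"p_spread": float("nan")},
            {"background_level": -1.0},
            {"soma_radius": (0.0, 1.0)},
            {"pixel_size": 0.0},
            {"n_cells": 5000},
        ],
    )
    def test_invalid_config_rejected(self, overrides):
        with pytest.raises(ConfigError):
            SyntheticConfig(image_shape=(300, 300), **overrides).validate()


class TestBrainSection:
    def test_empty_subcortical_layout_gives_all_cortical(self):
        shape = (420, 420)
        region = np.full(shape, REGION_CORTICAL, dtype=np.uint8)
        layout = RegionMask(region=region, footprint=np.ones(shape, bool), pixel_size=1.0)
        cfg = SyntheticConfig(n_cells=40, image_shape=shape, seed=3)
        _, truth, _ = generate_brain_section(cfg, layout)
        assert set(truth["region"]) == {"CORTICAL"}

    def test_full_frame_section_area_arithmetic(self):
        layout = full_frame_layout((1000, 1000), pixel_size=10.0)
        assert layout.section_area_mm2 == pytest.approx(100.0)

    def test_region_layout_must_partition_footprint(self):
        shape = (50, 50)
        region = np.zeros(shape, dtype=np.uint8)  # footprint pixels unlabelled
        with pytest.raises(ImageIOError, match="partition"):
            RegionMask(region=region, footprint=np.ones(shape, bool), pixel_size=1.0)

    def test_per_region_recipient_counts_match_resampling_oracle(self):
        shape = shape_for(80, footprint_fraction=0.6)
        cfg = SyntheticConfig(
            n_cells=80, image_shape=shape, p_spread=0.1, noise_sd=0.0, seed=17
        )
        layout = brain_slice_layout(shape, cfg.pixel_size)
        _, truth, _ = generate_brain_section(cfg, layout)
        donor, recipient, mch = _section_class_oracle(
            17, 80, cfg.p_mcherry, cfg.p_transduce, 0.1
        )
        assert (truth["true_class"] == "RECIPIENT").sum() == recipient.sum()
        assert (truth["true_class"] == "DONOR").sum() == donor.sum()
        np.testing.assert_array_equal(truth["mcherry_pos"].to_numpy(), mch)
        # Region split is a deterministic function of placement: recipients
        # per region must equal the truth-table tally.
        recips = truth[truth["true_class"] == "RECIPIENT"]
        by_region = recips["region"].value_counts().to_dict()
        assert sum(by_region.values()) == recipient.sum()

    def test_recipients_require_mcherry(self):
        shape = shape_for(80, footprint_fraction=0.6)
        cfg = SyntheticConfig(
            n_cells=80, image_shape=shape, p_mcherry=0.5, p_spread=1.0, seed=23
        )
        layout = brain_slice_layout(shape, cfg.pixel_size)
        _, truth, _ = generate_brain_section(cfg, layout)
        recips = truth[truth["true_class"] == "RECIPIENT"]
        assert recips["mcherry_pos"].all()


class TestFixtureSuite:
    def test_same_seed_gives_byte_identical_truth_tables(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_fixture_suite(a, seed=7)
        generate_fixture_suite(b, seed=7)
        truths = sorted(p.name for p in a.glob("*_truth.csv"))
        assert truths
        for name in truths:
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_manifest_lists_every_written_fixture(self, fixture_suite):
        out, manifest = fixture_suite
        listed = set()
        for entry in manifest["fixtures"].values():
            for key in ("image", "ground_truth", "region_mask", "table"):
                if entry.get(key):
                    listed.add(entry[key])
        on_disk = {
            p.name for p in out.iterdir()
            if p.name != "manifest.json" and not p.name.endswith(".tif.json")
        }
        assert listed == on_disk
        assert json.loads((out / "manifest.json").read_text())["fixtures"]

    def test_neurite_fixture_records_analytic_lengths(self, fixture_suite):
        out, manifest = fixture_suite
        truth = pd.read_csv(out / manifest["fixtures"]["neurite_field"]["ground_truth"])
        # Straight 200-px horizontal neurite at 0.5 µm/px: 100 µm of tree.
        straight = truth.loc[truth["neuron_id"] == 1, "expected_total_um"].iloc[0]
        assert straight == pytest.approx(100.0, rel=0.02)
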