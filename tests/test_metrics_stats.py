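"""Summary metrics, ΔΔCT, and the group-comparison statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from synspread import (
    RegionMask,
    compute_spread_metrics,
    count_recipients_by_region,
    delta_delta_ct,
    full_frame_layout,
    group_compare,
    normalize_to_control,
)
from synspread.metrics import MetricsError, aggregate_region_counts
from synspread.stats import StatsError, one_way_anova, tukey_hsd, two_sample_t


def _classified(n_donor=0, n_recipient=0, n_untransduced=0, n_ambiguous=0):
    labels = (
        ["DONOR"] * n_donor
        + ["RECIPIENT"] * n_recipient
        + ["UNTRANSDUCED"] * n_untransduced
        + ["AMBIGUOUS"] * n_ambiguous
    )
    return pd.DataFrame({
        "cell_id": np.arange(1, len(labels) + 1),
        "class_label": labels,
        "centroid_row": np.zeros(len(labels)),
        "centroid_col": np.zeros(len(labels)),
    })


class TestSpreadMetrics:
    def test_transduction_efficiency_arithmetic(self):
        m = compute_spread_metrics(_classified(120, 30, 50))
        assert m.transduction_efficiency == pytest.approx(0.60)
        assert m.spread_fraction == pytest.approx(30 / 80)
        assert m.n_gated == 200

    def test_zero_recipients_give_zero_spread(self):
        m = compute_spread_metrics(_classified(120, 0, 80))
        assert m.spread_fraction == 0.0

    def test_ambiguous_excluded_from_denominators(self):
        m = compute_spread_metrics(_classified(60, 10, 30, n_ambiguous=100))
        assert m.n_ambiguous == 100
        assert m.transduction_efficiency == pytest.approx(0.60)
        assert m.spread_fraction == pytest.approx(0.25)

    def test_total_denominator_option(self):
        m = compute_spread_metrics(_classified(60, 10, 30), denominator="total")
        assert m.spread_fraction == pytest.approx(0.10)

    def test_zero_gated_cells_raise(self):
        with pytest.raises(MetricsError, match="zero"):
            compute_spread_metrics(_classified())


class TestNormalizeToControl:
    def test_control_normalised_to_mean_one(self):
        out = normalize_to_control([2.0, 4.0], [2.0, 4.0])
        np.testing.assert_allclose(out, [2 / 3, 4 / 3])
        assert out.mean() == pytest.approx(1.0)

    def test_treated_scaled_by_control_mean(self):
        np.testing.assert_allclose(
            normalize_to_control([1.0, 1.0, 1.0], [2.0, 2.0]), [0.5, 0.5, 0.5]
        )

    def test_zero_control_mean_raises(self):
        with pytest.raises(MetricsError, match="zero"):
            normalize_to_control([1.0], [0.0, 0.0])


class TestRegionCounts:
    def _mask(self):
        return full_frame_layout((100, 100), pixel_size=10.0, cortical_fraction=0.5)

    def test_counts_conserve_total(self):
        rows = [(10.0, 50.0)] * 6 + [(80.0, 50.0)] * 4
        records = pd.DataFrame({
            "cell_id": np.arange(1, 11),
            "class_label": ["RECIPIENT"] * 10,
            "centroid_row": [r for r, _ in rows],
            "centroid_col": [c for _, c in rows],
        })
        counts = count_recipients_by_region(records, self._mask())
        assert counts["cortical"] == 6
        assert counts["subcortical"] == 4
        assert counts["whole_brain"] == 10

    def test_empty_subcortical_region(self):
        mask = full_frame_layout((100, 100), pixel_size=10.0, cortical_fraction=1.0)
        records = _classified(n_recipient=5)
        records["centroid_row"] = 10.0
        records["centroid_col"] = 10.0
        counts = count_recipients_by_region(records, mask)
        assert counts["subcortical"] == 0
        assert counts["cortical"] == 5

    def test_centroid_outside_footprint_counted_as_none(self):
        region = np.zeros((100, 100), np.uint8)
        region[:50] = 1
        region[50:] = 2
        footprint = np.ones((100, 100), bool)
        footprint[:, 90:] = False
        region[:, 90:] = 0
        mask = RegionMask(region=region, footprint=footprint, pixel_size=1.0)
        records = _classified(n_recipient=2)
        records["centroid_row"] = [10.0, 10.0]
        records["centroid_col"] = [10.0, 95.0]
        counts = count_recipients_by_region(records, mask)
        assert counts["outside_footprint"] == 1
        assert counts["whole_brain"] == 1

    def test_aggregate_sums_sections(self):
        base = {"cortical": 2, "subcortical": 3, "outside_footprint": 0,
                "whole_brain": 5, "section_area_mm2": 1.5}
        total = aggregate_region_counts([base, base])
        assert total["whole_brain"] == 10
        assert total["section_areas_mm2"] == [1.5, 1.5]


class TestDeltaDeltaCt:
    def _table(self):
        return pd.DataFrame({
            "ct_target": [20.0, 21.0, 25.0, 26.0],
            "ct_reference": [18.0, 19.0, 18.0, 19.0],
            "group": ["CONTROL", "CONTROL", "TREATED", "TREATED"],
        })

    def test_control_sample_at_group_mean_is_unity(self):
        out = delta_delta_ct(self._table())
        control = out[out["group"] == "CONTROL"]
        # Both control samples share ΔCT = 2 -> relative expression 1.
        np.testing.assert_allclose(control["relative_expression"], 1.0)

    def test_known_fold_change(self):
        table = pd.DataFrame({
            "ct_target": [13.0, 15.0],
            "ct_reference": [10.0, 10.0],
            "group": ["CONTROL", "TREATED"],
        })
        out = delta_delta_ct(table)
        assert out.loc[1, "relative_expression"] == pytest.approx(0.25)

    def test_matches_spreadsheet_style_recomputation(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame({
            "ct_target": rng.uniform(18, 30, 12),
            "ct_reference": rng.uniform(14, 20, 12),
            "group": ["CONTROL"] * 6 + ["TREATED"] * 6,
        })
        out = delta_delta_ct(table)
        # Independent row-by-row recomputation with plain Python floats.
        dcts = [t - r for t, r in zip(table["ct_target"], table["ct_reference"])]
        control_mean = sum(dcts[:6]) / 6
        for i, dct in enumerate(dcts):
            assert out["relative_expression"].iloc[i] == pytest.approx(
                2.0 ** (-(dct - control_mean)), rel=1e-12
            )

    def test_control_geometric_mean_is_one(self):
        out = delta_delta_ct(self._table())
        control = out[out["group"] == "CONTROL"]["relative_expression"]
        assert np.exp(np.log(control).mean()) == pytest.approx(1.0)

    def test_ct_shift_invariance(self):
        base = delta_delta_ct(self._table())
        shifted_table = self._table()
        shifted_table["ct_target"] += 3.0
        shifted_table["ct_reference"] += 3.0
        shifted = delta_delta_ct(shifted_table)
        np.testing.assert_allclose(
            base["relative_expression"], shifted["relative_expression"]
        )

    def test_requires_control_rows_and_valid_cts(self):
        bad = self._table()
        bad["group"] = "TREATED"
        with pytest.raises(MetricsError, match="control"):
            delta_delta_ct(bad)
        neg = self._table()
        neg.loc[0, "ct_target"] = -1.0
        with pytest.raises(MetricsError, match="positive"):
            delta_delta_ct(neg)


class TestGroupCompare:
    def test_identical_groups_give_zero_t_and_p_one(self):
        result = group_compare({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_identical_groups_give_zero_f(self):
        result = group_compare(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]},
            design="MULTI_GROUP",
        )
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_t_matches_reference_implementation(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 2, rng.integers(3, 12))
            t, p, _ = two_sample_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_f_matches_reference_implementation(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            groups = [rng.normal(rng.normal(), 1, rng.integers(3, 10))
                      for _ in range(4)]
            f, p, _, _ = one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert f == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_tukey_matches_reference_implementation(self):
        rng = np.random.default_rng(17)
        groups = {n: rng.normal(m, 1, 8) for n, m in
                  (("a", 0.0), ("b", 0.8), ("c", 1.5))}
        ours = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups.values())
        pairs = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        for _, row in ours.iterrows():
            i, j = pairs[(row["group_a"], row["group_b"])]
            assert row["p_value"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_small_groups_rejected(self):
        with pytest.raises(StatsError, match="fewer than 2"):
            group_compare({"a": [1.0], "b": [1.0, 2.0]})

    def test_multi_group_returns_posthoc_pairs(self):
        rng = np.random.default_rng(19)
        result = group_compare(
            {n: rng.normal(i, 1, 6) for i, n in enumerate("abc")},
            design="MULTI_GROUP",
        )
        assert result.posthoc is not None
        assert len(result.posthoc) == 3
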