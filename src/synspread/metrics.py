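"""Summary quantities: transduction efficiency, spread, region counts, ΔΔCT.

Definitions (over the gated cell population):

- transduction efficiency = donors / (donors + recipients + untransduced);
- spread fraction = recipients / (recipients + untransduced), i.e. the
  fraction of eGFP-negative gated cells that acquired the tagged protein
  (configurable to a per-total-cells denominator);
- AMBIGUOUS cells are excluded from both denominators and reported.

Spread values are normalised to the mean of the control condition, so the
control group's normalised mean is 1 by construction. In vivo recipient
counts are reported per region (cortical / subcortical, summed to whole
brain) with the section area in mm² as a comparability check, not as a
divisor.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .gating import (
    CLASS_AMBIGUOUS,
    CLASS_DONOR,
    CLASS_RECIPIENT,
    CLASS_UNTRANSDUCED,
)
from .image_io import REGION_NAMES, RegionMask

DENOMINATOR_NON_DONOR = "non_donor"
DENOMINATOR_TOTAL = "total"


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class SpreadMetrics:
    n_gated: int
    n_donor: int
    n_recipient: int
    n_untransduced: int
    n_ambiguous: int
    transduction_efficiency: float
    spread_fraction: float
    condition: str = ""
    normalized_spread: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def compute_spread_metrics(
    records: pd.DataFrame,
    condition: str = "",
    denominator: str = DENOMINATOR_NON_DONOR,
) -> SpreadMetrics:
    """Counts and fractions from classified cell records.

    Cells labelled UNSET (e.g. outside the in vivo mCherry gate) are not
    part of the gated population. Raises on zero gated cells.
    """
    labels = records["class_label"] if "class_label" in records else pd.Series(dtype=str)
    n_donor = int((labels == CLASS_DONOR).sum())
    n_recipient = int((labels == CLASS_RECIPIENT).sum())
    n_untransduced = int((labels == CLASS_UNTRANSDUCED).sum())
    n_ambiguous = int((labels == CLASS_AMBIGUOUS).sum())
    n_gated = n_donor + n_recipient + n_untransduced + n_ambiguous
    if n_gated == 0:
        raise MetricsError("zero gated cells: nothing to summarise")
    denom_all = n_donor + n_recipient + n_untransduced
    transduction = n_donor / denom_all if denom_all else float("nan")
    if denominator == DENOMINATOR_NON_DONOR:
        denom_spread = n_recipient + n_untransduced
    elif denominator == DENOMINATOR_TOTAL:
        denom_spread = denom_all
    else:
        raise MetricsError(f"unknown spread denominator {denominator!r}")
    spread = n_recipient / denom_spread if denom_spread else float("nan")
    return SpreadMetrics(
        n_gated=n_gated,
        n_donor=n_donor,
        n_recipient=n_recipient,
        n_untransduced=n_untransduced,
        n_ambiguous=n_ambiguous,
        transduction_efficiency=transduction,
        spread_fraction=spread,
        condition=condition,
    )


def normalize_to_control(values, control_values) -> np.ndarray:
    """Divide each value by the mean of the control replicates."""
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise MetricsError("control group is empty")
    mean = control.mean()
    if mean == 0:
        raise MetricsError("control mean is zero; cannot normalise")
    return values / mean


def count_recipients_by_region(
    records: pd.DataFrame, region_mask: RegionMask
) -> dict:
    """Assign each recipient to the region containing its centroid.

    Returns per-region counts, the whole-brain count (cortical +
    subcortical), the number of recipients falling outside the section
    footprint (counted as NONE and reported), and the section area in mm²
    as the section-size QC quantity.
    """
    recipients = records[records.get("class_label") == CLASS_RECIPIENT]
    counts = {"CORTICAL": 0, "SUBCORTICAL": 0, "NONE": 0}
    h, w = region_mask.region.shape
    for _, row in recipients.iterrows():
        r = int(round(row["centroid_row"]))
        c = int(round(row["centroid_col"]))
        if not (0 <= r < h and 0 <= c < w) or not region_mask.footprint[r, c]:
            counts["NONE"] += 1
            continue
        counts[REGION_NAMES[int(region_mask.region[r, c])]] += 1
    return {
        "cortical": counts["CORTICAL"],
        "subcortical": counts["SUBCORTICAL"],
        "outside_footprint": counts["NONE"],
        "whole_brain": counts["CORTICAL"] + counts["SUBCORTICAL"],
        "section_area_mm2": region_mask.section_area_mm2,
    }


def aggregate_region_counts(per_section: list[dict]) -> dict:
    """Sum recipient counts across the sections of one animal."""
    if not per_section:
        raise MetricsError("no sections to aggregate")
    out = {
        key: int(sum(s[key] for s in per_section))
        for key in ("cortical", "subcortical", "outside_footprint", "whole_brain")
    }
    out["section_areas_mm2"] = [s["section_area_mm2"] for s in per_section]
    return out


def delta_delta_ct(table: pd.DataFrame, control_group: str = "CONTROL") -> pd.DataFrame:
    """Relative expression by the ΔΔCT method.

    Expects columns ct_target, ct_reference, group. Per sample:
    ΔCT = CT_target − CT_reference; ΔΔCT = ΔCT − mean(ΔCT of control
    group); relative expression = 2^(−ΔΔCT). The control group's
    geometric-mean relative expression is 1 by construction.
    """
    required = {"ct_target", "ct_reference", "group"}
    missing = required - set(table.columns)
    if missing:
        raise MetricsError(f"CT table lacks columns {sorted(missing)}")
    ct_t = table["ct_target"].to_numpy(float)
    ct_r = table["ct_reference"].to_numpy(float)
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_r))):
        raise MetricsError("CT values must be finite")
    if np.any(ct_t <= 0) or np.any(ct_r <= 0):
        raise MetricsError("CT values must be positive")
    control = table["group"] == control_group
    if not control.any():
        raise MetricsError(f"no rows in control group {control_group!r}")
    out = table.copy()
    out["delta_ct"] = ct_t - ct_r
    control_mean = float(out.loc[control, "delta_ct"].mean())
    out["delta_delta_ct"] = out["delta_ct"] - control_mean
    out["relative_expression"] = np.power(2.0, -out["delta_delta_ct"])
    return out
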