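"""Donor / recipient / untransduced gating, puncta scoring, annexin index.

In vitro (reporter construct co-expressing eGFP and HA-tagged
α-synuclein A53T via P2A, over morphology-positive cells):

=========  =====  ====
class      eGFP   HA
=========  =====  ====
DONOR        +     +
RECIPIENT    −     +
UNTRANSD.    −     −
AMBIGUOUS    +     −
=========  =====  ====

AMBIGUOUS (eGFP+ without HA, unexpected under P2A co-expression) is
counted and reported but excluded from every denominator. Positivity is a
strict inequality on background-subtracted means versus the calibrated
threshold — a cell exactly at threshold is negative.

In vivo (knockdown-reporter mCherry, then the same construct): cells
failing the mCherry gate are UNSET (outside the reporting population);
recipients are mCherry+ / eGFP− / HA+.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk, white_tophat

from .image_io import LabelMap, MultiChannelImage
from .intensity import CLASS_UNSET, ThresholdSet

CLASS_DONOR = "DONOR"
CLASS_RECIPIENT = "RECIPIENT"
CLASS_UNTRANSDUCED = "UNTRANSDUCED"
CLASS_AMBIGUOUS = "AMBIGUOUS"

MODE_IN_VITRO = "IN_VITRO"
MODE_IN_VIVO = "IN_VIVO"


@dataclass(frozen=True)
class GatingScheme:
    """Channel roles for one gating mode."""

    mode: str = MODE_IN_VITRO
    egfp_channel: str = "eGFP"
    ha_channel: str = "HA"
    mcherry_channel: str = "mCherry"

    @property
    def required_channels(self) -> tuple[str, ...]:
        if self.mode == MODE_IN_VITRO:
            return (self.egfp_channel, self.ha_channel)
        return (self.mcherry_channel, self.egfp_channel, self.ha_channel)


def _positive(records: pd.DataFrame, channel: str, thresholds: ThresholdSet):
    col = f"bg_sub_{channel}"
    if col not in records.columns:
        raise KeyError(f"records carry no column {col!r}")
    return records[col].to_numpy(float) > thresholds[channel].threshold


def classify_in_vitro(
    records: pd.DataFrame,
    thresholds: ThresholdSet,
    scheme: GatingScheme | None = None,
) -> pd.DataFrame:
    """Set class_label by the eGFP x HA gating table (strict thresholds)."""
    scheme = scheme or GatingScheme(mode=MODE_IN_VITRO)
    records = records.copy()
    if records.empty:
        return records
    egfp = _positive(records, scheme.egfp_channel, thresholds)
    ha = _positive(records, scheme.ha_channel, thresholds)
    label = np.where(
        egfp & ha, CLASS_DONOR,
        np.where(~egfp & ha, CLASS_RECIPIENT,
                 np.where(~egfp & ~ha, CLASS_UNTRANSDUCED, CLASS_AMBIGUOUS)),
    )
    records["class_label"] = label
    return records


def classify_in_vivo(
    records: pd.DataFrame,
    thresholds: ThresholdSet,
    scheme: GatingScheme | None = None,
) -> pd.DataFrame:
    """In vivo gating: mCherry gate first, then the eGFP x HA table.

    mCherry-negative cells stay UNSET; RECIPIENT is mCherry+/eGFP−/HA+.
    """
    scheme = scheme or GatingScheme(mode=MODE_IN_VIVO)
    records = records.copy()
    if records.empty:
        return records
    mch = _positive(records, scheme.mcherry_channel, thresholds)
    egfp = _positive(records, scheme.egfp_channel, thresholds)
    ha = _positive(records, scheme.ha_channel, thresholds)
    label = np.where(
        ~mch, CLASS_UNSET,
        np.where(egfp & ha, CLASS_DONOR,
                 np.where(~egfp & ha, CLASS_RECIPIENT,
                          np.where(~egfp & ~ha, CLASS_UNTRANSDUCED,
                                   CLASS_AMBIGUOUS))),
    )
    records["class_label"] = label
    return records


@dataclass(frozen=True)
class PunctaParams:
    """Aggregate-puncta detection parameters.

    White top-hat of the given radius isolates compact bright structures;
    a punctum is a connected component, inside the cell footprint eroded
    by the top-hat radius, whose top-hat intensity exceeds the cell's
    top-hat mean + k_sigma·sd and whose area is at least min_puncta_area.
    A cell is aggregate-positive with >= min_puncta_per_cell puncta.
    """

    tophat_radius: int = 3
    k_sigma: float = 3.0
    min_puncta_area: float = 4.0
    min_puncta_per_cell: int = 2


def detect_puncta(
    image: MultiChannelImage,
    channel: str,
    labels: LabelMap,
    records: pd.DataFrame,
    params: PunctaParams | None = None,
) -> tuple[pd.DataFrame, float]:
    """Count aggregation puncta per cell and score aggregate positivity.

    Returns the records with ``puncta_count`` and ``aggregate_positive``
    set, plus the percentage of aggregate-positive cells.
    """
    params = params or PunctaParams()
    lab = labels.labels
    arr = image.channel(channel).astype(np.float64)
    if lab.shape != arr.shape:
        raise ValueError("label map and image shapes differ")
    records = records.copy()
    if records.empty:
        records["aggregate_positive"] = pd.Series(dtype=bool)
        return records, 0.0

    areas = records["area_px2"].to_numpy(float)
    typical_radius = float(np.sqrt(np.median(areas) / np.pi))
    if params.tophat_radius >= typical_radius:
        warnings.warn(
            f"tophat_radius {params.tophat_radius} px >= typical soma radius "
            f"{typical_radius:.1f} px; puncta may be erased",
            stacklevel=2,
        )

    tophat = white_tophat(arr, footprint=disk(params.tophat_radius))
    eroded = ndimage.grey_erosion(
        lab, footprint=disk(params.tophat_radius)
    )  # labels surviving erosion: interior of each cell
    interior = eroded == lab

    counts = np.zeros(len(records), dtype=int)
    for i, cid in enumerate(records["cell_id"].to_numpy(int)):
        cell = lab == cid
        vals = tophat[cell]
        thr = float(vals.mean() + params.k_sigma * vals.std())
        candidates = cell & interior & (tophat > max(thr, 0.0)) & (tophat > 0)
        comp, n = ndimage.label(candidates)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        counts[i] = int(np.sum(sizes >= params.min_puncta_area))

    records["puncta_count"] = counts
    records["aggregate_positive"] = counts >= params.min_puncta_per_cell
    pct = 100.0 * float(records["aggregate_positive"].mean())
    return records, pct


def annexin_imaging_index(
    image: MultiChannelImage,
    fitc_channel: str,
    morphology_channel: str,
    labels: LabelMap,
    background_exclusion_px: int = 5,
) -> float:
    """Per-field annexin-V index: ΣFITC / Σmorphology over cell footprints.

    Both sums are background-subtracted (median background away from
    cells). The ratio is invariant to scaling both channels by a common
    constant; downstream it is normalised to the control condition mean.
    """
    lab = labels.labels
    fitc = image.channel(fitc_channel).astype(np.float64)
    morph = image.channel(morphology_channel).astype(np.float64)
    if lab.shape != fitc.shape:
        raise ValueError("label map and image shapes differ")
    cell_fg = lab > 0
    if not cell_fg.any():
        raise ValueError("no cell footprints: morphology segmentation is empty")
    far = ndimage.distance_transform_edt(~cell_fg) > background_exclusion_px
    bg_mask = (~cell_fg) & far
    if not bg_mask.any():
        bg_mask = ~cell_fg
    n_px = int(cell_fg.sum())
    fitc_sum = float(fitc[cell_fg].sum() - np.median(fitc[bg_mask]) * n_px)
    morph_sum = float(morph[cell_fg].sum() - np.median(morph[bg_mask]) * n_px)
    if morph_sum <= 0:
        raise ValueError("no morphology signal above background in cell footprints")
    return max(fitc_sum, 0.0) / morph_sum
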