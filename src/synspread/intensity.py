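"""Per-cell intensity measurement and control-derived positivity thresholds.

Per cell and channel the raw mean over the label footprint is recorded,
together with a background-subtracted mean. Background is the median
intensity of pixels at least 5 px away from any cell (median rather than
mean: robust to dim debris), and background-subtracted values are floored
at zero.

Positivity thresholds are calibrated from control populations — the
fluorescence of non-transduced cells for the eGFP gate, secondary-
antibody-only staining for the HA gate — by either an empirical
percentile (linear interpolation) or mean + k·sd of the control
distribution. Threshold provenance (control description, rule, parameter,
control n) is retained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import LabelMap, MultiChannelImage

CLASS_UNSET = "UNSET"

RULE_PERCENTILE = "PERCENTILE_OF_CONTROL"
RULE_MEAN_K_SD = "MEAN_PLUS_K_SD"

#: Below this many control cells a threshold is flagged low-confidence.
DEFAULT_CONTROL_FLOOR = 20


class CalibrationError(ValueError):
    pass


@dataclass
class ThresholdEntry:
    """One channel's positivity threshold with its provenance."""

    channel: str
    threshold: float
    rule: str
    parameter: float
    n_control_cells: int
    control_description: str = ""
    low_confidence: bool = False
    flagged_constant: bool = False


@dataclass
class ThresholdSet:
    """Per-channel thresholds; serialises to/from JSON."""

    entries: dict[str, ThresholdEntry] = field(default_factory=dict)

    def add(self, entry: ThresholdEntry) -> None:
        self.entries[entry.channel] = entry

    def __getitem__(self, channel: str) -> ThresholdEntry:
        try:
            return self.entries[channel]
        except KeyError:
            raise CalibrationError(
                f"no threshold calibrated for channel {channel!r}; "
                f"available: {sorted(self.entries)}"
            ) from None

    def __contains__(self, channel: str) -> bool:
        return channel in self.entries

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {ch: asdict(e) for ch, e in sorted(self.entries.items())}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        payload = json.loads(Path(path).read_text())
        ts = cls()
        for ch, entry in payload.items():
            ts.add(ThresholdEntry(**entry))
        return ts


def measure_cell_intensities(
    image: MultiChannelImage,
    labels: LabelMap,
    background_exclusion_px: int = 5,
) -> pd.DataFrame:
    """Per-cell raw and background-subtracted mean intensities.

    Returns one row per label with cell_id, centroid, areas, and for each
    channel ``raw_mean_<ch>`` and ``bg_sub_<ch>`` (floored at 0). The
    class_label column starts UNSET and puncta_count at 0. Background per
    channel is the median over label-0 pixels eroded
    ``background_exclusion_px`` away from any cell.
    """
    lab = labels.labels
    if lab.shape != image.shape:
        raise ValueError(
            f"label map shape {lab.shape} does not match image shape {image.shape}"
        )
    ids = labels.label_ids
    if ids.size == 0:
        cols = ["cell_id", "centroid_row", "centroid_col", "area_px2", "area_um2",
                "class_label", "puncta_count", "region"]
        for ch in image.channels:
            cols += [f"raw_mean_{ch}", f"net_mean_{ch}", f"bg_sub_{ch}"]
        return pd.DataFrame(columns=cols)

    cell_fg = lab > 0
    if background_exclusion_px > 0:
        far = ndimage.distance_transform_edt(~cell_fg) > background_exclusion_px
    else:
        far = ~cell_fg
    bg_mask = ~cell_fg & far
    if not bg_mask.any():
        bg_mask = ~cell_fg  # crowded frame: fall back to all non-cell pixels

    centroids = ndimage.center_of_mass(np.ones_like(lab), lab, index=ids)
    areas = ndimage.sum_labels(np.ones_like(lab), lab, index=ids).astype(float)
    out = {
        "cell_id": ids.astype(int),
        "centroid_row": [c[0] for c in centroids],
        "centroid_col": [c[1] for c in centroids],
        "area_px2": areas,
        "area_um2": areas * image.pixel_size**2,
        "class_label": [CLASS_UNSET] * ids.size,
        "puncta_count": np.zeros(ids.size, dtype=int),
        "region": ["NONE"] * ids.size,
    }
    for ch, arr in image.channels.items():
        arr = arr.astype(np.float64)
        raw = ndimage.mean(arr, lab, index=ids)
        background = float(np.median(arr[bg_mask]))
        out[f"raw_mean_{ch}"] = raw
        # net_mean keeps the sign; bg_sub is floored at zero. Thresholds are
        # calibrated on net_mean (a symmetric noise distribution), gated on
        # bg_sub — identical decisions since thresholds are non-negative.
        out[f"net_mean_{ch}"] = raw - background
        out[f"bg_sub_{ch}"] = np.maximum(raw - background, 0.0)
    return pd.DataFrame(out)


def sample_control_patches(
    image: MultiChannelImage,
    channels: list[str],
    n_patches: int = 200,
    radius: float = 8.0,
    seed: int = 0,
    background_exclusion_px: int = 5,
) -> pd.DataFrame:
    """Soma-sized random discs from a control image, measured like cells.

    Used when the control preparation contains no segmentable cells (e.g.
    a vehicle-injected brain section): the staining level of soma-sized
    patches stands in for the control cell population.
    """
    rng = np.random.default_rng(seed)
    h, w = image.shape
    margin = int(np.ceil(radius)) + 1
    rows = rng.uniform(margin, h - margin, n_patches)
    cols = rng.uniform(margin, w - margin, n_patches)
    lab = np.zeros((h, w), dtype=np.int32)
    # Paint patches sequentially; overlaps keep the later id (harmless for
    # a background-level estimate).
    for i, (r, c) in enumerate(zip(rows, cols), start=1):
        r0, r1 = int(np.floor(r - radius)) - 1, int(np.ceil(r + radius)) + 2
        c0, c1 = int(np.floor(c - radius)) - 1, int(np.ceil(c + radius)) + 2
        r0, c0 = max(r0, 0), max(c0, 0)
        rr, cc = np.mgrid[r0:min(r1, h), c0:min(c1, w)]
        sel = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
        lab[r0:min(r1, h), c0:min(c1, w)][sel] = i
    sub = MultiChannelImage(
        channels={ch: image.channel(ch) for ch in channels},
        pixel_size=image.pixel_size,
        bit_depth=image.bit_depth,
    )
    return measure_cell_intensities(
        sub, LabelMap(labels=lab, provenance="AUTO"),
        background_exclusion_px=background_exclusion_px,
    )


def calibrate_threshold(
    control_values,
    rule: str = RULE_PERCENTILE,
    param: float = 99.0,
    channel: str = "",
    control_description: str = "",
    control_floor: int = DEFAULT_CONTROL_FLOOR,
) -> ThresholdEntry:
    """Derive one channel's positivity threshold from control intensities.

    PERCENTILE_OF_CONTROL: empirical percentile with linear interpolation,
    ``param`` in (50, 100]. MEAN_PLUS_K_SD: mean + k·sd (sample sd,
    ddof=1), ``param`` = k > 0. Constant controls under MEAN_PLUS_K_SD
    yield that constant and are flagged.
    """
    values = np.asarray(control_values, dtype=float)
    if values.size == 0:
        raise CalibrationError("empty control population")
    if not np.all(np.isfinite(values)):
        raise CalibrationError("control values must be finite")
    flagged = False
    if rule == RULE_PERCENTILE:
        if not 50.0 < param <= 100.0:
            raise CalibrationError(f"percentile must be in (50, 100], got {param}")
        threshold = float(np.percentile(values, param))
    elif rule == RULE_MEAN_K_SD:
        if not param > 0:
            raise CalibrationError(f"k must be > 0, got {param}")
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        if sd == 0.0:
            threshold = float(values.mean())
            flagged = True
        else:
            threshold = float(values.mean() + param * sd)
    else:
        raise CalibrationError(f"unknown rule {rule!r}")
    return ThresholdEntry(
        channel=channel,
        threshold=max(threshold, 0.0),
        rule=rule,
        parameter=float(param),
        n_control_cells=int(values.size),
        control_description=control_description,
        low_confidence=values.size < control_floor,
        flagged_constant=flagged,
    )


def flow_gate_index(
    events: pd.DataFrame,
    control_events: pd.DataFrame,
    gate_channel: str = "mCherry",
    signal_channel: str = "FITC",
    gate_percentile: float = 99.0,
    statistic: str = "median",
) -> float:
    """Summary of reporter-positive events' annexin-V (FITC) signal.

    The reporter-positive gate threshold is the ``gate_percentile`` of the
    non-expressing control events' gate-channel values; the index is the
    median (configurable to mean) signal of gated events. Normalising one
    condition's index to the control condition's is left to the caller
    (``normalize_to_control``). Raises when the gate captures no events.
    """
    if events.empty or control_events.empty:
        raise CalibrationError("flow event tables must be non-empty")
    gate = float(np.percentile(control_events[gate_channel].to_numpy(float),
                               gate_percentile))
    gated = events.loc[events[gate_channel].to_numpy(float) > gate, signal_channel]
    if gated.empty:
        raise CalibrationError(
            f"gate {gate_channel} > {gate:.3g} (percentile {gate_percentile} of "
            f"controls) captured zero of {len(events)} events"
        )
    values = gated.to_numpy(float)
    if statistic == "median":
        return float(np.median(values))
    if statistic == "mean":
        return float(np.mean(values))
    raise CalibrationError(f"unknown statistic {statistic!r}")
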