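"""Cell-body detection from the morphology channel.

Somata are segmented by adaptive (local-mean) thresholding of the
morphology stain: a pixel is foreground when it exceeds the arithmetic
mean of a square window around it by more than a fixed offset. Connected
components outside an area window are discarded, touching cells can be
split by a distance-transform watershed, and labels are renumbered in
raster order of each component's first pixel so output labelling is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import ImageIOError, LabelMap, MultiChannelImage


@dataclass(frozen=True)
class SegmentationParams:
    """Adaptive-threshold segmentation parameters.

    window: side of the local-mean square window (odd, >= 3), px.
    offset: ADU above the local mean required for foreground.
    min_area / max_area: component area limits, px².
    split_touching: apply a distance-transform watershed to split
        touching somata, seeded at distance peaks at least
        ``peak_min_distance`` apart.
    """

    window: int = 51
    offset: float = 10.0
    min_area: float = 50.0
    max_area: float = 20000.0
    split_touching: bool = False
    peak_min_distance: int = 8


def _renumber_raster(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K in raster order of each label's first pixel."""
    flat = labels.ravel()
    nonzero = np.flatnonzero(flat)
    if nonzero.size == 0:
        return np.zeros_like(labels, dtype=np.int32)
    ids, first = np.unique(flat[nonzero], return_index=True)
    order = np.argsort(nonzero[first])
    mapping = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    mapping[ids[order]] = np.arange(1, ids.size + 1, dtype=np.int32)
    return mapping[labels]


def segment_somata(
    image: MultiChannelImage,
    morphology_channel: str,
    params: SegmentationParams | None = None,
) -> LabelMap:
    """Detect cell bodies in the morphology channel.

    Local-mean thresholding makes the result invariant to constant
    intensity offsets. Raises for a missing channel or a window that does
    not fit the image.
    """
    params = params or SegmentationParams()
    channel = image.channel(morphology_channel).astype(np.float64)
    if params.window < 3 or params.window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {params.window}")
    if params.window >= min(channel.shape):
        raise ValueError(
            f"window {params.window} does not fit image of shape {channel.shape}"
        )
    local_mean = ndimage.uniform_filter(channel, size=params.window, mode="reflect")
    mask = channel > local_mean + params.offset

    labels, _ = ndimage.label(mask)
    if params.split_touching:
        labels = _watershed_split(mask, labels, params.peak_min_distance)

    # Area filter.
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    bad = ids[(counts < params.min_area) | (counts > params.max_area)]
    if bad.size:
        labels[np.isin(labels, bad)] = 0

    return LabelMap(labels=_renumber_raster(labels), provenance="AUTO")


def _watershed_split(mask: np.ndarray, labels: np.ndarray, peak_min_distance: int):
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=peak_min_distance, labels=labels, exclude_border=False
    )
    markers = np.zeros_like(labels)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return labels
    return watershed(-distance, markers=markers, mask=mask)


def check_companion_shape(labels: LabelMap, image: MultiChannelImage) -> None:
    """Raise when a label mask does not match its companion image frame."""
    if labels.labels.shape != image.shape:
        raise ImageIOError(
            f"label mask shape {labels.labels.shape} does not match image shape "
            f"{image.shape}"
        )
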