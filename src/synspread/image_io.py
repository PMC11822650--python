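"""Containers and disk formats for multi-channel fluorescence images.

Images travel as multi-page TIFFs (one page per channel) with a JSON
sidecar recording channel names, pixel size (µm/pixel) and bit depth.
Label maps are single-page integer TIFFs. Region masks (cortical /
subcortical partitions of a brain-section footprint) are label TIFFs with
a small JSON sidecar of their own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

# Region codes used throughout.
REGION_NONE = 0
REGION_CORTICAL = 1
REGION_SUBCORTICAL = 2
REGION_NAMES = {REGION_NONE: "NONE", REGION_CORTICAL: "CORTICAL",
                REGION_SUBCORTICAL: "SUBCORTICAL"}


class ImageIOError(ValueError):
    """Raised for malformed image, label or region files."""


@dataclass
class MultiChannelImage:
    """Named 2D fluorescence channels sharing one frame and pixel grid.

    Parameters
    ----------
    channels
        Mapping channel name -> 2D intensity array (ADU). All channels
        must share the same shape and be non-negative.
    pixel_size
        Physical size of one pixel in µm.
    bit_depth
        Nominal acquisition bit depth (default 16).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.channels:
            raise ImageIOError("image must contain at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ImageIOError(f"channels must be 2D, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ImageIOError(f"channel shapes differ: {shapes}")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ImageIOError(f"pixel_size must be positive, got {self.pixel_size}")
        for name, arr in self.channels.items():
            if np.min(arr) < 0:
                raise ImageIOError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ImageIOError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None


@dataclass
class LabelMap:
    """Integer-labelled segmentation of cell bodies; 0 is background."""

    labels: np.ndarray
    provenance: str = "AUTO"  # AUTO | MANUAL

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ImageIOError(f"label map must be integer, got dtype {labels.dtype}")
        if labels.ndim != 2:
            raise ImageIOError("label map must be 2D")
        if labels.min() < 0:
            raise ImageIOError("label map contains negative labels")
        self.labels = labels

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.label_ids.size)


@dataclass
class RegionMask:
    """Cortical/subcortical partition of a brain-section footprint.

    ``region`` holds REGION_CORTICAL / REGION_SUBCORTICAL codes inside the
    section footprint and REGION_NONE outside; the footprint itself is the
    section-size QC quantity (area in mm²).
    """

    region: np.ndarray
    footprint: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        region = np.asarray(self.region)
        footprint = np.asarray(self.footprint, dtype=bool)
        if region.shape != footprint.shape:
            raise ImageIOError("region and footprint shapes differ")
        if self.pixel_size <= 0:
            raise ImageIOError("pixel_size must be positive")
        valid = {REGION_NONE, REGION_CORTICAL, REGION_SUBCORTICAL}
        if not set(np.unique(region)).issubset(valid):
            raise ImageIOError(f"region codes must be within {sorted(valid)}")
        # Partition requirement: every footprint pixel carries a region code
        # and no code appears outside the footprint.
        if np.any((region > 0) & ~footprint) or np.any((region == 0) & footprint):
            raise ImageIOError(
                "region layout is not a partition of the section footprint"
            )
        self.region = region
        self.footprint = footprint

    @property
    def section_area_mm2(self) -> float:
        return float(self.footprint.sum()) * (self.pixel_size / 1000.0) ** 2


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: MultiChannelImage, path: str | Path) -> Path:
    """Write a multi-page TIFF (one page per channel) plus JSON sidecar."""
    path = Path(path)
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "channels": names,
        "pixel_size_um": image.pixel_size,
        "bit_depth": image.bit_depth,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def read_image(path: str | Path) -> MultiChannelImage:
    """Read a multi-page TIFF written by :func:`write_image`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ImageIOError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    names = meta["channels"]
    if len(names) != stack.shape[0]:
        raise ImageIOError(
            f"sidecar names {len(names)} channels but TIFF has {stack.shape[0]} pages"
        )
    return MultiChannelImage(
        channels={n: stack[i] for i, n in enumerate(names)},
        pixel_size=float(meta["pixel_size_um"]),
        bit_depth=int(meta.get("bit_depth", 16)),
    )


def write_label_map(label_map: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    labels = label_map.labels
    if labels.max() > np.iinfo(np.uint16).max:
        raise ImageIOError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def import_label_mask(path: str | Path) -> LabelMap:
    """Load a manually drawn label image (integer TIFF) as a LabelMap."""
    arr = tifffile.imread(Path(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise ImageIOError(
            f"label mask {path} has non-integer pixels (dtype {arr.dtype})"
        )
    return LabelMap(labels=arr.astype(np.int32), provenance="MANUAL")


def write_region_mask(mask: RegionMask, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.region.astype(np.uint8))
    meta = {"pixel_size_um": mask.pixel_size, "codes": REGION_NAMES}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def read_region_mask(path: str | Path) -> RegionMask:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    region = tifffile.imread(path).astype(np.uint8)
    return RegionMask(
        region=region, footprint=region > 0, pixel_size=float(meta["pixel_size_um"])
    )
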