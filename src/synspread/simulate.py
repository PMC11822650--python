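"""Synthetic multi-channel microscopy with known ground truth.

Emulates the assays this pipeline quantifies: cultured neurons carrying a
dual reporter (eGFP co-expressed with HA-tagged α-synuclein A53T via P2A),
brain-section mosaics with an mCherry knockdown reporter, aggregate-puncta
fields, neurite fields with analytically known lengths, and flow-style
event tables. Every generator returns a ground-truth table that downstream
recovery tests treat as the oracle.

Generative model
----------------
Cell bodies are discs (radius ~ N(mean, sd)) placed by rejection sampling
with a minimum centre separation; disc edges are softened by a Gaussian
blur of sigma 1 px. Per cell, class is drawn as DONOR with probability
``p_transduce``, otherwise RECIPIENT with probability ``p_spread``,
otherwise UNTRANSDUCED. Donor somata carry eGFP and HA signal, recipients
HA only, untransduced neither; all cells carry the morphology marker.
A flat background plus optional Poisson shot noise and additive Gaussian
read noise is applied, and frames are quantised to unsigned 16-bit.

Randomness: each call derives four independent child streams from the one
seed — (1) placement (one uniform position pair per attempt, then the n
radius normals), (2) class (n transduction uniforms, then n spread
uniforms), (3) per-cell intensity multipliers (one lognormal vector per
channel in channel order), (4) pixel noise. The class stream is therefore
reproducible by an independent re-sampling script regardless of how many
placement attempts were rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_io import (
    REGION_CORTICAL,
    REGION_NAMES,
    REGION_NONE,
    REGION_SUBCORTICAL,
    MultiChannelImage,
    RegionMask,
    write_image,
    write_region_mask,
)

CLASS_DONOR = "DONOR"
CLASS_RECIPIENT = "RECIPIENT"
CLASS_UNTRANSDUCED = "UNTRANSDUCED"

_EDGE_SIGMA = 1.0  # px, soma edge softening
_BLUR_TRUNCATE = 4.0  # blur support; beyond 4*sigma the spill is exactly zero


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested min_separation."""


class ConfigError(ValueError):
    """Raised for invalid synthetic-data configurations."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic field.

    Intensity levels are soma signal amplitudes above background, in ADU.
    Defaults mirror the assay this emulates: 60% transduction efficiency,
    bright (1000 ADU) donor reporters over a 100 ADU background, read
    noise at 5% of the donor signal.
    """

    n_cells: int = 200
    image_shape: tuple[int, int] = (640, 640)
    pixel_size: float = 1.0  # µm per pixel
    p_transduce: float = 0.6
    p_spread: float = 0.2
    p_mcherry: float = 0.9  # knockdown-reporter coverage (brain sections)
    morphology_level: float = 800.0
    donor_egfp_level: float = 1000.0
    donor_ha_level: float = 1000.0
    recipient_ha_level: float = 600.0
    mcherry_level: float = 800.0
    level_cv: float = 0.15  # lognormal cell-to-cell expression variability
    background_level: float = 100.0
    noise_sd: float = 50.0
    poisson_noise: bool = False
    soma_radius: tuple[float, float] = (8.0, 1.0)  # mean, sd in px
    min_separation: float = 26.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_transduce", "p_spread", "p_mcherry"):
            p = getattr(self, name)
            if not (np.isfinite(p) and 0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name in (
            "morphology_level", "donor_egfp_level", "donor_ha_level",
            "recipient_ha_level", "mcherry_level", "background_level",
            "noise_sd", "level_cv",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")
        if self.soma_radius[0] <= 0:
            raise ConfigError("soma_radius mean must be > 0")
        if self.pixel_size <= 0 or not np.isfinite(self.pixel_size):
            raise ConfigError("pixel_size must be > 0")
        if self.min_separation <= 0:
            raise ConfigError("min_separation must be > 0")
        # Coarse capacity check: random sequential placement saturates well
        # below square packing; demand ~3x headroom up front.
        h, w = self.image_shape
        margin = self.soma_radius[0] + 4 * self.soma_radius[1] + _BLUR_TRUNCATE
        usable = max(h - 2 * margin, 0) * max(w - 2 * margin, 0)
        if self.n_cells > 0 and usable < 3.0 * self.n_cells * 0.5 * self.min_separation**2:
            raise ConfigError(
                f"image {self.image_shape} too small to place {self.n_cells} cells "
                f"at min_separation={self.min_separation}"
            )

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


def shape_for(n_cells: int, min_separation: float = 26.0,
              soma_radius: tuple[float, float] = (8.0, 1.0),
              footprint_fraction: float = 1.0) -> tuple[int, int]:
    """Smallest square frame that comfortably holds ``n_cells`` somata.

    ``footprint_fraction`` discounts the usable area when cells are
    confined to a section footprint (the elliptical brain-slice layout
    covers ~0.66 of the frame).
    """
    margin = soma_radius[0] + 4 * soma_radius[1] + _BLUR_TRUNCATE
    side = int(
        np.ceil(np.sqrt(3.2 * n_cells * 0.5 * min_separation**2 / footprint_fraction))
    ) + int(2 * margin) + 2
    return (side, side)


def _spawn_streams(seed: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(4)]


def _draw_radii(rng: np.random.Generator, cfg: SyntheticConfig, n: int) -> np.ndarray:
    """Soma radii ~ N(mean, sd), clipped to mean +/- 2 sd (and >= 1 px).

    The clip bounds the soma footprint so that, at the default
    min_separation, the 4-sigma blur support of one cell's signal can
    never reach a neighbour's footprint: recipient eGFP stays exactly at
    background in noiseless frames.
    """
    mean, sd = cfg.soma_radius
    r = rng.normal(mean, sd, n)
    return np.clip(r, max(mean - 2 * sd, 1.0), mean + 2 * sd)


def _place_cells(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_separation: float,
    margin: float,
    footprint: np.ndarray | None = None,
    max_tries_per_cell: int = 500,
) -> np.ndarray:
    """Rejection-sample ``n`` centres with pairwise distance >= min_separation."""
    if n == 0:
        return np.zeros((0, 2))
    cell = float(max(min_separation, 1.0))
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    pts: list[tuple[float, float]] = []
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise PlacementError(f"frame {shape} too small for margin {margin:.1f}")
    min_sq = min_separation**2
    tries = 0
    budget = max_tries_per_cell * n
    while len(pts) < n:
        if tries >= budget:
            raise PlacementError(
                f"placed only {len(pts)}/{n} cells after {budget} attempts; "
                f"reduce min_separation={min_separation} or enlarge the frame"
            )
        tries += 1
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if footprint is not None and not footprint[int(r), int(c)]:
            continue
        gi, gj = int(r // cell), int(c // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for rr, cc in grid.get((gi + di, gj + dj), ()):
                    if (rr - r) ** 2 + (cc - c) ** 2 < min_sq:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts.append((r, c))
            grid.setdefault((gi, gj), []).append((r, c))
    return np.asarray(pts)


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float):
    """Slice + boolean mask of the disc, clipped to the frame."""
    r0 = max(int(np.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 2, shape[0])
    c0 = max(int(np.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return (slice(r0, r1), slice(c0, c1)), mask


def _render_somata(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Additively paint discs, then soften edges with a sigma-1 blur."""
    img = np.zeros(shape, dtype=np.float64)
    for (r, c), rad, amp in zip(centers, radii, amplitudes):
        if amp <= 0:
            continue
        sl, mask = _disc_mask(shape, (r, c), rad)
        img[sl][mask] += amp
    if centers.shape[0]:
        img = gaussian_filter(img, _EDGE_SIGMA, truncate=_BLUR_TRUNCATE)
    return img


def _finalize(
    noiseless: dict[str, np.ndarray],
    cfg: SyntheticConfig,
    noise_rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Apply shot/read noise and quantise to uint16, channel by channel."""
    out = {}
    for name, arr in noiseless.items():
        img = arr.astype(np.float64)
        if cfg.poisson_noise:
            img = noise_rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if cfg.noise_sd > 0:
            img = img + noise_rng.normal(0.0, cfg.noise_sd, size=img.shape)
        out[name] = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return out


def _true_means(
    noiseless_uint: dict[str, np.ndarray],
    centers: np.ndarray,
    radii: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-cell mean of each quantised noiseless channel over the soma disc."""
    shape = next(iter(noiseless_uint.values())).shape
    means = {name: np.zeros(len(centers)) for name in noiseless_uint}
    for i, ((r, c), rad) in enumerate(zip(centers, radii)):
        sl, mask = _disc_mask(shape, (r, c), rad)
        for name, arr in noiseless_uint.items():
            means[name][i] = float(arr[sl][mask].mean())
    return means


def _quantise_noiseless(noiseless: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {
        n: np.clip(np.rint(a), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        for n, a in noiseless.items()
    }


def generate_culture(config: SyntheticConfig) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Synthetic transduced culture: channels NFH (morphology), eGFP, HA.

    Returns the image and a GroundTruth table with one row per cell:
    cell_id, true_class, row/col centre, radius, and the true (noiseless)
    per-channel soma mean intensities ``true_<channel>`` including
    background. Donors carry eGFP+HA, recipients HA only, untransduced
    neither; every cell is NFH+.
    """
    config.validate()
    place_rng, class_rng, level_rng, noise_rng = _spawn_streams(config.seed)
    n = config.n_cells
    shape = config.image_shape
    margin = config.soma_radius[0] + 4 * config.soma_radius[1] + _BLUR_TRUNCATE
    centers = _place_cells(place_rng, n, shape, config.min_separation, margin)
    radii = _draw_radii(place_rng, config, n)

    u_transduce = class_rng.random(n)
    u_spread = class_rng.random(n)
    donor = u_transduce < config.p_transduce
    recipient = ~donor & (u_spread < config.p_spread)
    classes = np.where(
        donor, CLASS_DONOR, np.where(recipient, CLASS_RECIPIENT, CLASS_UNTRANSDUCED)
    )

    sigma = config.level_cv
    mult = {
        ch: level_rng.lognormal(-0.5 * sigma**2, sigma, n) if sigma > 0 else np.ones(n)
        for ch in ("NFH", "eGFP", "HA")
    }
    amp_nfh = config.morphology_level * mult["NFH"]
    amp_egfp = np.where(donor, config.donor_egfp_level * mult["eGFP"], 0.0)
    amp_ha = np.where(
        donor, config.donor_ha_level * mult["HA"],
        np.where(recipient, config.recipient_ha_level * mult["HA"], 0.0),
    )

    bg = config.background_level
    noiseless = {
        "NFH": bg + _render_somata(shape, centers, radii, amp_nfh),
        "eGFP": bg + _render_somata(shape, centers, radii, amp_egfp),
        "HA": bg + _render_somata(shape, centers, radii, amp_ha),
    }
    clean_uint = _quantise_noiseless(noiseless)
    truth_means = _true_means(clean_uint, centers, radii)

    channels = _finalize(noiseless, config, noise_rng)
    image = MultiChannelImage(channels=channels, pixel_size=config.pixel_size)

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "true_class": classes,
            "row": centers[:, 0] if n else np.zeros(0),
            "col": centers[:, 1] if n else np.zeros(0),
            "radius": radii,
            "region": [REGION_NAMES[REGION_NONE]] * n,
            "true_NFH": truth_means["NFH"],
            "true_eGFP": truth_means["eGFP"],
            "true_HA": truth_means["HA"],
        }
    )
    return image, truth


def full_frame_layout(
    shape: tuple[int, int], pixel_size: float, cortical_fraction: float = 0.5
) -> RegionMask:
    """Footprint = the full frame; top band of rows is CORTICAL."""
    region = np.full(shape, REGION_SUBCORTICAL, dtype=np.uint8)
    split = int(round(cortical_fraction * shape[0]))
    region[:split, :] = REGION_CORTICAL
    return RegionMask(region=region, footprint=np.ones(shape, bool), pixel_size=pixel_size)


def brain_slice_layout(
    shape: tuple[int, int], pixel_size: float, core_fraction: float = 0.62
) -> RegionMask:
    """Elliptical section footprint; outer ring CORTICAL, inner core SUBCORTICAL.

    ``core_fraction`` is the normalised elliptical radius of the
    cortex/subcortex boundary (cortex is the outer shell, as in a coronal
    section).
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    rho = np.sqrt(
        ((rr - (h - 1) / 2) / (0.46 * h)) ** 2 + ((cc - (w - 1) / 2) / (0.46 * w)) ** 2
    )
    footprint = rho <= 1.0
    region = np.zeros(shape, dtype=np.uint8)
    region[footprint & (rho > core_fraction)] = REGION_CORTICAL
    region[footprint & (rho <= core_fraction)] = REGION_SUBCORTICAL
    return RegionMask(region=region, footprint=footprint, pixel_size=pixel_size)


def generate_brain_section(
    config: SyntheticConfig, region_layout: RegionMask
) -> tuple[MultiChannelImage, pd.DataFrame, RegionMask]:
    """Synthetic brain-section mosaic: channels mCherry, eGFP, HA.

    Each cell is mCherry+ with probability ``p_mcherry`` (knockdown-reporter
    coverage). Class draw mirrors the culture generator, except a cell can
    only become a RECIPIENT if it is mCherry+ (recipients are defined inside
    the reporter-covered population). GroundTruth rows carry region labels
    taken from the layout at the cell centre, plus an ``mcherry_pos`` flag.

    Draw order on the class stream: n mCherry uniforms, n transduction
    uniforms, n spread uniforms.
    """
    config.validate()
    if region_layout.region.shape != tuple(config.image_shape):
        raise ConfigError(
            f"region layout shape {region_layout.region.shape} != image shape "
            f"{tuple(config.image_shape)}"
        )
    place_rng, class_rng, level_rng, noise_rng = _spawn_streams(config.seed)
    n = config.n_cells
    shape = config.image_shape
    margin = config.soma_radius[0] + 4 * config.soma_radius[1] + _BLUR_TRUNCATE
    centers = _place_cells(
        place_rng, n, shape, config.min_separation, margin,
        footprint=region_layout.footprint,
    )
    radii = _draw_radii(place_rng, config, n)

    u_mcherry = class_rng.random(n)
    u_transduce = class_rng.random(n)
    u_spread = class_rng.random(n)
    mcherry_pos = u_mcherry < config.p_mcherry
    donor = u_transduce < config.p_transduce
    recipient = ~donor & mcherry_pos & (u_spread < config.p_spread)
    classes = np.where(
        donor, CLASS_DONOR, np.where(recipient, CLASS_RECIPIENT, CLASS_UNTRANSDUCED)
    )

    sigma = config.level_cv
    mult = {
        ch: level_rng.lognormal(-0.5 * sigma**2, sigma, n) if sigma > 0 else np.ones(n)
        for ch in ("mCherry", "eGFP", "HA")
    }
    amp_mcherry = np.where(mcherry_pos, config.mcherry_level * mult["mCherry"], 0.0)
    amp_egfp = np.where(donor, config.donor_egfp_level * mult["eGFP"], 0.0)
    amp_ha = np.where(
        donor, config.donor_ha_level * mult["HA"],
        np.where(recipient, config.recipient_ha_level * mult["HA"], 0.0),
    )

    bg = config.background_level
    noiseless = {
        "mCherry": bg + _render_somata(shape, centers, radii, amp_mcherry),
        "eGFP": bg + _render_somata(shape, centers, radii, amp_egfp),
        "HA": bg + _render_somata(shape, centers, radii, amp_ha),
    }
    clean_uint = _quantise_noiseless(noiseless)
    truth_means = _true_means(clean_uint, centers, radii)
    channels = _finalize(noiseless, config, noise_rng)
    image = MultiChannelImage(channels=channels, pixel_size=config.pixel_size)

    region_codes = (
        region_layout.region[
            centers[:, 0].astype(int), centers[:, 1].astype(int)
        ] if n else np.zeros(0, dtype=int)
    )
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "true_class": classes,
            "row": centers[:, 0] if n else np.zeros(0),
            "col": centers[:, 1] if n else np.zeros(0),
            "radius": radii,
            "mcherry_pos": mcherry_pos,
            "region": [REGION_NAMES[int(c)] for c in region_codes],
            "true_mCherry": truth_means["mCherry"],
            "true_eGFP": truth_means["eGFP"],
            "true_HA": truth_means["HA"],
        }
    )
    return image, truth, region_layout


def generate_puncta_field(
    config: SyntheticConfig,
    puncta_fraction: float = 0.15,
    n_puncta: int = 3,
    puncta_amplitude_factor: float = 10.0,
    puncta_radius: float = 1.2,
) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Culture field in which a known fraction of cells bear bright HA puncta.

    All cells are HA-stained at ``recipient_ha_level``; exactly
    ``round(puncta_fraction * n_cells)`` of them (the first cells in
    placement order after a seeded shuffle) additionally carry ``n_puncta``
    compact aggregates at ``puncta_amplitude_factor`` × the soma HA level.
    Puncta are painted after the edge blur: aggregates are compact and
    high-contrast by construction.
    """
    config.validate()
    if not 0.0 <= puncta_fraction <= 1.0:
        raise ConfigError("puncta_fraction must be in [0, 1]")
    place_rng, class_rng, level_rng, noise_rng = _spawn_streams(config.seed)
    n = config.n_cells
    shape = config.image_shape
    margin = config.soma_radius[0] + 4 * config.soma_radius[1] + _BLUR_TRUNCATE
    centers = _place_cells(place_rng, n, shape, config.min_separation, margin)
    radii = _draw_radii(place_rng, config, n)
    n_pos = int(round(puncta_fraction * n))
    order = class_rng.permutation(n)
    has_puncta = np.zeros(n, dtype=bool)
    has_puncta[order[:n_pos]] = True

    sigma = config.level_cv
    mult = {
        ch: level_rng.lognormal(-0.5 * sigma**2, sigma, n) if sigma > 0 else np.ones(n)
        for ch in ("NFH", "HA")
    }
    amp_nfh = config.morphology_level * mult["NFH"]
    amp_ha = config.recipient_ha_level * mult["HA"]

    bg = config.background_level
    nfh = bg + _render_somata(shape, centers, radii, amp_nfh)
    ha = bg + _render_somata(shape, centers, radii, amp_ha)

    # Crisp puncta, painted after the soma edge blur, well inside the soma.
    for i in np.flatnonzero(has_puncta):
        amp = puncta_amplitude_factor * amp_ha[i]
        ring = max(radii[i] - 4.0, 0.0) * 0.85
        for k in range(n_puncta):
            ang = 2 * np.pi * k / n_puncta
            pr = centers[i, 0] + ring * np.sin(ang)
            pc = centers[i, 1] + ring * np.cos(ang)
            sl, mask = _disc_mask(shape, (pr, pc), puncta_radius)
            ha[sl][mask] += amp

    noiseless = {"NFH": nfh, "HA": ha}
    clean_uint = _quantise_noiseless(noiseless)
    truth_means = _true_means(clean_uint, centers, radii)
    channels = _finalize(noiseless, config, noise_rng)
    image = MultiChannelImage(channels=channels, pixel_size=config.pixel_size)

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "true_class": [CLASS_RECIPIENT] * n,
            "row": centers[:, 0] if n else np.zeros(0),
            "col": centers[:, 1] if n else np.zeros(0),
            "radius": radii,
            "region": [REGION_NAMES[REGION_NONE]] * n,
            "has_puncta": has_puncta,
            "n_puncta": np.where(has_puncta, n_puncta, 0),
            "true_NFH": truth_means["NFH"],
            "true_HA": truth_means["HA"],
        }
    )
    return image, truth


def generate_annexin_field(
    config: SyntheticConfig, fitc_ratio: float = 0.5
) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Field whose FITC (annexin-V) signal is a known ratio of NFH per cell."""
    config.validate()
    place_rng, class_rng, level_rng, noise_rng = _spawn_streams(config.seed)
    n = config.n_cells
    shape = config.image_shape
    margin = config.soma_radius[0] + 4 * config.soma_radius[1] + _BLUR_TRUNCATE
    centers = _place_cells(place_rng, n, shape, config.min_separation, margin)
    radii = _draw_radii(place_rng, config, n)
    sigma = config.level_cv
    mult = level_rng.lognormal(-0.5 * sigma**2, sigma, n) if sigma > 0 else np.ones(n)
    amp_nfh = config.morphology_level * mult
    amp_fitc = fitc_ratio * amp_nfh  # same per-cell multiplier: exact ratio

    bg = config.background_level
    noiseless = {
        "NFH": bg + _render_somata(shape, centers, radii, amp_nfh),
        "FITC": bg + _render_somata(shape, centers, radii, amp_fitc),
    }
    clean_uint = _quantise_noiseless(noiseless)
    truth_means = _true_means(clean_uint, centers, radii)
    channels = _finalize(noiseless, config, noise_rng)
    image = MultiChannelImage(channels=channels, pixel_size=config.pixel_size)
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "row": centers[:, 0] if n else np.zeros(0),
            "col": centers[:, 1] if n else np.zeros(0),
            "radius": radii,
            "fitc_ratio": fitc_ratio,
            "true_NFH": truth_means["NFH"],
            "true_FITC": truth_means["FITC"],
        }
    )
    return image, truth


# --------------------------------------------------------------------------
# Neurite fields with analytically known lengths
# --------------------------------------------------------------------------

def _draw_polyline(img: np.ndarray, points: list[tuple[float, float]], value: float) -> None:
    """Paint a 1-px-wide polyline (Bresenham per segment)."""
    from skimage.draw import line

    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        rr, cc = line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        img[rr, cc] = np.maximum(img[rr, cc], value)


def generate_neurite_field(
    pixel_size: float = 0.5,
    background_level: float = 100.0,
    signal_level: float = 1000.0,
    soma_radius: float = 8.0,
) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Deterministic morphology field with analytically known neurite lengths.

    Three neurons on a quiet background:

    1. one straight horizontal neurite of 200 px of skeleton,
    2. one 45° diagonal neurite of 100 diagonal steps,
    3. a Y-tree: a 60-px horizontal trunk branching into two 50-px limbs
       (one horizontal, one diagonal).

    The truth table lists, per neuron, the expected total tree length and
    the expected single-neurite (root-to-farthest-tip geodesic) length in
    µm under the chain-code metric (1 px orthogonal, √2 px diagonal).
    """
    shape = (360, 360)
    img = np.zeros(shape, dtype=np.float64)
    soma_centers = [(60.0, 60.0), (180.0, 60.0), (290.0, 60.0)]
    for ctr in soma_centers:
        sl, mask = _disc_mask(shape, ctr, soma_radius)
        img[sl][mask] = signal_level

    r0 = soma_radius
    # Neuron 1: horizontal neurite, 200 px of skeleton beyond the soma edge.
    start = (60.0, 60.0 + r0 + 1)
    _draw_polyline(img, [start, (60.0, start[1] + 199)], signal_level)
    len1_total = 199 * pixel_size
    # Neuron 2: diagonal neurite, 100 diagonal steps.
    start = (180.0 - (r0 + 1) * np.sqrt(0.5), 60.0 + (r0 + 1) * np.sqrt(0.5))
    sr, sc = int(round(start[0])), int(round(start[1]))
    _draw_polyline(img, [(sr, sc), (sr - 100, sc + 100)], signal_level)
    len2_total = 100 * np.sqrt(2.0) * pixel_size
    # Neuron 3: Y-tree. Trunk 60 px horizontal, then 50 px horizontal limb
    # and 50-diagonal-step limb.
    start = (290.0, 60.0 + r0 + 1)
    fork = (290.0, start[1] + 60)
    _draw_polyline(img, [start, fork], signal_level)
    _draw_polyline(img, [fork, (290.0, fork[1] + 50)], signal_level)
    _draw_polyline(img, [fork, (290.0 - 50, fork[1] + 50)], signal_level)
    trunk = 60 * pixel_size
    limb_h = 50 * pixel_size
    limb_d = 50 * np.sqrt(2.0) * pixel_size
    len3_total = trunk + limb_h + limb_d
    len3_single = trunk + limb_d  # geodesic to the farthest tip

    channels = {
        "NFH": np.clip(np.rint(background_level + img), 0, 65535).astype(np.uint16)
    }
    image = MultiChannelImage(channels=channels, pixel_size=pixel_size)
    truth = pd.DataFrame(
        {
            "neuron_id": [1, 2, 3],
            "row": [c[0] for c in soma_centers],
            "col": [c[1] for c in soma_centers],
            "n_primary_neurites": [1, 1, 1],
            "expected_total_um": [len1_total, len2_total, len3_total],
            "expected_single_um": [len1_total, len2_total, len3_single],
        }
    )
    return image, truth


def generate_flow_events(
    n_events: int = 20000,
    mcherry_pos_fraction: float = 0.5,
    mcherry_neg_level: float = 100.0,
    mcherry_pos_level: float = 5000.0,
    fitc_median: float = 1000.0,
    fitc_neg_median: float = 200.0,
    sigma: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Flow-cytometry-style event table (mCherry, FITC per event).

    mCherry is lognormal around a dim (non-expressing) or bright
    (expressing) level; FITC of expressing events is lognormal with the
    requested median, so the gated-median oracle is exact up to sampling.
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(mcherry_pos_fraction * n_events))
    pos = np.zeros(n_events, dtype=bool)
    pos[:n_pos] = True
    rng.shuffle(pos)
    mcherry = np.where(
        pos,
        rng.lognormal(np.log(mcherry_pos_level), sigma, n_events),
        rng.lognormal(np.log(mcherry_neg_level), sigma, n_events),
    )
    fitc = np.where(
        pos,
        rng.lognormal(np.log(fitc_median), sigma, n_events),
        rng.lognormal(np.log(fitc_neg_median), sigma, n_events),
    )
    return pd.DataFrame(
        {"mCherry": mcherry, "FITC": fitc, "true_expressing": pos}
    )


# --------------------------------------------------------------------------
# Fixture suite
# --------------------------------------------------------------------------

FIXTURE_SUITE_VERSION = 1


def generate_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the versioned fixture set used by the recovery tests.

    Contents: noiseless culture, noisy culture, brain section, puncta
    field (15% of cells bearing puncta, noiseless), neurite field with
    analytically known lengths, non-transduced control culture, secondary-
    antibody-only control image, control brain section (no virus), and a
    flow event table. A manifest lists every file with its ground-truth
    table and the generation parameters. Same seed -> byte-identical
    ground-truth tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": FIXTURE_SUITE_VERSION, "seed": seed, "fixtures": {}}

    def record(name: str, image_path: Path, truth: pd.DataFrame | None, config: dict,
               extra: dict | None = None) -> None:
        entry = {"image": image_path.name, "params": config}
        if truth is not None:
            tpath = out / f"{name}_truth.csv"
            truth.to_csv(tpath, index=False)
            entry["ground_truth"] = tpath.name
        if extra:
            entry.update(extra)
        manifest["fixtures"][name] = entry

    base = SyntheticConfig(n_cells=80, image_shape=(420, 420), seed=seed)

    cfg = base.replace(noise_sd=0.0)
    img, truth = generate_culture(cfg)
    record("culture_noiseless", write_image(img, out / "culture_noiseless.tif"),
           truth, dataclasses.asdict(cfg))

    cfg = base.replace(seed=seed + 1)
    img, truth = generate_culture(cfg)
    record("culture_noisy", write_image(img, out / "culture_noisy.tif"),
           truth, dataclasses.asdict(cfg))

    cfg = base.replace(n_cells=120, image_shape=(560, 560), noise_sd=0.0, seed=seed + 2)
    layout = brain_slice_layout(cfg.image_shape, cfg.pixel_size)
    img, truth, mask = generate_brain_section(cfg, layout)
    rpath = write_region_mask(mask, out / "brain_section_regions.tif")
    record("brain_section_noiseless", write_image(img, out / "brain_section.tif"),
           truth, dataclasses.asdict(cfg), extra={"region_mask": rpath.name})

    cfg = base.replace(
        n_cells=100, image_shape=(520, 520), noise_sd=0.0,
        soma_radius=(10.0, 1.0), min_separation=30.0, seed=seed + 3,
    )
    img, truth = generate_puncta_field(cfg, puncta_fraction=0.15)
    record("puncta_field", write_image(img, out / "puncta_field.tif"),
           truth, {**dataclasses.asdict(cfg), "puncta_fraction": 0.15})

    img, truth = generate_neurite_field()
    record("neurite_field", write_image(img, out / "neurite_field.tif"),
           truth, {"pixel_size": 0.5})

    # Controls: non-transduced culture (eGFP threshold source) doubling as
    # the secondary-antibody-only HA control, plus a cell-free section.
    cfg = base.replace(p_transduce=0.0, p_spread=0.0, seed=seed + 4)
    img, truth = generate_culture(cfg)
    record("control_nontransduced", write_image(img, out / "control_nontransduced.tif"),
           truth, dataclasses.asdict(cfg))

    cfg = base.replace(n_cells=0, seed=seed + 5)
    img, truth = generate_culture(cfg)
    record("control_secondary_only", write_image(img, out / "control_secondary_only.tif"),
           truth, dataclasses.asdict(cfg))

    cfg = base.replace(
        n_cells=0, image_shape=(560, 560), noise_sd=0.0, seed=seed + 6
    )
    layout = brain_slice_layout(cfg.image_shape, cfg.pixel_size)
    img, truth, mask = generate_brain_section(cfg, layout)
    record("control_section", write_image(img, out / "control_section.tif"),
           truth, dataclasses.asdict(cfg))

    events = generate_flow_events(seed=seed + 7)
    epath = out / "flow_events.csv"
    events.to_csv(epath, index=False)
    manifest["fixtures"]["flow_events"] = {
        "image": None, "table": epath.name,
        "params": {"seed": seed + 7, "fitc_median": 1000.0},
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
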