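# Methods

## Scope and design

The package quantifies reporter-based cell-to-cell spread of tagged
α-synuclein from multi-channel 2D fluorescence images. It is organised
as a library of testable stages (synthetic data, segmentation,
morphometry, intensity/calibration, gating, metrics, statistics) with an
orchestration layer and CLI on top, and is validated exclusively against
a synthetic microscopy generator whose ground truth is known by
construction. Numbered scripts under `analysis/` present the experiments
as a narrative; all computation lives in `src/synspread/` so tests and
the acceptance script exercise the same code paths.

## Synthetic data generator

The generator emulates the statistical structure of the assay, not its
optics.

**Geometry.** Cell bodies are discs with radius ~ N(8, 1) px (clipped to
±2 sd), placed by rejection sampling with a minimum centre separation of
26 px; disc edges are softened with a Gaussian blur of σ = 1 px
(truncated at 4σ). At 1 µm/px this gives soma areas of ~200 µm²,
realistic for cortical neurons. The separation minus the maximal
footprint radius exceeds the blur support, so in noiseless frames a
cell's reporter signal never reaches a neighbour's footprint: recipient
eGFP equals background *exactly*, which the oracle tests rely on.
Neurites are 1-px polylines drawn only in dedicated morphometry fields,
where their chain-code lengths are analytic.

**Classes.** Per cell: DONOR with probability `p_transduce`
(default 0.6, the assay's reported transduction efficiency), otherwise
RECIPIENT with probability `p_spread`, otherwise UNTRANSDUCED. Donors
carry eGFP and HA, recipients HA only, untransduced neither; all cells
carry the morphology marker. Brain-section fields replace NFH with an
mCherry knockdown reporter expressed with probability `p_mcherry`
(default 0.9); a cell can only be a recipient inside the
reporter-positive population, matching the in vivo counting rule.

**Intensities and noise.** Signal amplitudes default to 1000 ADU
(donor eGFP/HA) over a 100 ADU background with per-cell lognormal
variability (CV 0.15) and recipient HA at 600 ADU (spread cargo is
dimmer than autonomous expression). Additive Gaussian read noise
defaults to 50 ADU — 5% of the donor signal, the stochastic study
condition — with optional Poisson shot noise; frames are quantised to
uint16. Acquisition bit depth and exposure are declared choices, not
inferred from any instrument.

**Randomness.** Each generator call derives four child streams from one
seed (placement, class, intensity, noise) with a documented draw order.
Child streams rather than a single serial stream make the class draws
reproducible by an independent re-sampling script regardless of how many
placement attempts were rejected; the tests include exactly such an
oracle. Identical (config, seed) gives bit-identical images and truth
tables.

**Ground truth.** The truth table records, per cell, the class, centre,
radius, region, and the mean of each *quantised noiseless* channel over
the soma disc — so the measurement oracle is exact up to pixel noise,
not up to rendering approximations.

**What the generator does not emulate.** No PSF or 3D structure, no
photobleaching, no spatially varying background or flat-field error, no
realistic neuronal morphology, no segmentation-hostile cell clumping
(touching-cell splitting exists but is off by default and exercised
separately). Passing tests therefore demonstrate correctness of the
*computations* under the stated statistical model, not robustness to
every property of real micrographs.

## Segmentation

Adaptive thresholding: foreground = pixel > local mean (51-px square
window) + offset (10 ADU), connected components labelled, area-filtered
(defaults 50–20000 px²), optionally split by a distance-transform
watershed seeded at distance peaks (off by default). Local-mean
thresholding makes the stage exactly invariant to constant intensity
offsets. Labels are renumbered 1..K in raster order of first pixel so
output labelling is deterministic. Manual label masks (integer TIFF) are
accepted verbatim as an alternative.

## Intensity measurement and calibration

Per cell and channel the raw mean over the label footprint is recorded.
Background is the *median* intensity of pixels ≥ 5 px away from any cell
(median for robustness to dim debris). Two derived columns are kept:
`net_mean` (raw − background, signed) and `bg_sub` (floored at zero).
Gating uses `bg_sub`; thresholds are calibrated on `net_mean`. The two
give identical gating decisions (thresholds are non-negative), but
calibrating on the signed values preserves the symmetric control noise
distribution — flooring first would halve the apparent control sd and
systematically lower a mean + k·sd threshold.

Rules: `PERCENTILE_OF_CONTROL` (empirical percentile, linear
interpolation; eGFP and mCherry gates default to 99) and
`MEAN_PLUS_K_SD` (sample sd, ddof = 1; HA background default k = 3).
Control populations: segmented non-transduced cultures in vitro; for
control-injected brain sections, which contain no segmentable cells,
soma-sized random patches of the section stand in for control cells.
Thresholds carry provenance (rule, parameter, control description,
control n; < 20 control cells is flagged low-confidence). Cells exactly
at threshold are negative.

## Gating

In vitro, over morphology-positive cells: donor = eGFP⁺∧HA⁺, recipient
= eGFP⁻∧HA⁺, untransduced = eGFP⁻∧HA⁻; eGFP⁺∧HA⁻ — unexpected under
P2A co-expression — is labelled AMBIGUOUS, reported, and excluded from
every denominator. In vivo the mCherry gate is applied first; cells
failing it are UNSET (outside the knockdown-reporting population) and
the remaining cells follow the same table. Classes partition the gated
population by construction.

## Puncta, annexin, flow

**Puncta.** A white top-hat (disk radius 3 px) isolates compact bright
structures; a punctum is a connected component with top-hat intensity
above the cell's top-hat mean + 3 sd and area ≥ 4 px²; a cell is
aggregate-positive with ≥ 2 puncta. The component search runs inside the
cell footprint eroded by the top-hat radius: the blurred soma rim
otherwise produces arc-shaped top-hat artefacts that masquerade as
puncta, while the statistics are taken over the full footprint so the
threshold is not inflated by the erosion. One code path serves HA and
proteostat-style positivity alike.

**Annexin-V imaging index.** Σ(background-subtracted FITC) /
Σ(background-subtracted morphology) over all cell footprints, per field;
invariant to common rescaling of both channels; downstream normalised to
the control-condition mean.

**Flow-style gating.** The reporter-positive gate is the 99th percentile
of non-expressing control events' mCherry; the index is the *median*
FITC of gated events (median chosen for robustness; configurable to
mean), normalised to the control condition.

## Metrics and statistics

Transduction efficiency = donors / (donors + recipients + untransduced).
Spread fraction = recipients / (recipients + untransduced) — recipients
among all eGFP⁻ gated cells; a per-total-cells denominator is available
as a configuration. Normalisation divides by the control-group mean, so
the control normalised mean is 1 identically. In vivo recipient counts
are absolute per brain (summed over sections) with the section area
(mm²) reported as a comparability check, not used as a divisor; a
region split assigns each recipient to the region containing its
centroid.

ΔΔCT: per sample ΔCT = CT_target − CT_reference, ΔΔCT = ΔCT − mean
control ΔCT, relative expression = 2^(−ΔΔCT); the control geometric mean
is 1 by construction and the result is invariant to adding a constant to
every CT of both genes.

Group comparisons implement the textbook formulas directly — pooled-
variance two-tailed Student t, one-way fixed-effects ANOVA F, Tukey HSD
on the studentized range — with scipy.stats supplying only the reference
distributions. Tests cross-check them against independent scipy
implementations. Degenerate inputs are defined: identical groups with
zero pooled variance give statistic 0 and p = 1.

## Morphometry

The morphology mask (median + offset threshold) minus soma footprints is
skeletonized; the skeleton's pixel graph uses chain-code weights (1
orthogonal, √2 diagonal), dropping diagonal edges that shortcut a
staircase corner so lengths are not double-counted. Each connected
skeleton piece is assigned whole to the soma nearest to any of its
pixels (branch-level, so a wandering tip cannot be reassigned). Primary
neurites are root clusters where the skeleton meets a 2-px dilation of
the soma boundary; the single-neurite length is the root-to-farthest-tip
geodesic per primary neurite, and the total tree length sums all
assigned segments. Straight, diagonal and Y-shaped test neurites recover
their analytic lengths within 0.5%, and 90°-rotation invariance is
exact. Whether per-field or per-neuron averages are wanted downstream is
left to the caller; the table is per neuron with areas in px² and µm².

## Study conditions and problem sizes

The validation experiments use the conditions the package documents as
its synthetic study design: noiseless oracle fields of 80 cells;
stochastic recovery on 1000-cell fields, 20 seeds per spread setting
p_spread ∈ {0.05, 0.1, 0.2, 0.4} at 50 ADU read noise; and a knockdown
analogue (control p_spread 0.2 vs depleted 0.05) with 5 replicate
~200-cell fields per condition — the assay quantifies on the order of
200 cell bodies per experiment — repeated 100 times. Thresholds are
calibrated once per experiment from two control fields, as control
cultures are separate preparations.

## Known limitations

- The adaptive-threshold statistic is the local arithmetic mean; other
  local statistics (median, Gaussian-weighted) are not provided.
- Touching-cell splitting is a plain distance-transform watershed; dense
  clumps beyond what the generator produces are untested.
- The spread denominator treats AMBIGUOUS cells as unusable rather than
  attempting rescue; with bright debris this can shrink denominators.
- Flow tables are plain CSV columns; no FCS parsing, compensation or
  spectral unmixing.
- All geometry is 2D; mosaics are assumed stitched upstream.
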