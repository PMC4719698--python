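# Methods

## The measurement model

A double-immunostained MSGB section carries three colour populations:
red chromogen over CD20+ B cells, brown DAB over CD3+ T cells, and a
bluish haematoxylin counterstain (plus unstained glass/fat, which reads
near-white). The quantity of interest per gland is the pair of
whole-section cell counts (B, T) and their ratio B/(B+T). The model
behind the pixel approach is deliberately simple: stained area is
proportional to cell number, with a chromogen-specific constant
(pixels per cell) that absorbs cell size, membrane-vs-cytoplasmic
staining pattern and detector sensitivity. The constant is estimated
once per staining protocol from a calibration panel and is not assumed
transferable across laboratories.

Assumptions, and where they bend: (1) linearity of stained area in cell
number — degrades in dense sheets (germinal centres) where cells touch
and the membrane signal fuses, which is why validation panels must
include dense images; (2) chromogens separable in colour space — red
and brown overlap in RGB, so red is detected on the Cr chrominance
channel and brown through a hue remap (below); (3) tissue-independent
background — haematoxylin and white glass both sit far from the red
region in Cr, so no tissue mask is needed for counting (a tissue mask
is only needed for areas, which this package reports as an unvalidated
convenience via the 0.46 µm/px scan scale).

## Pipeline stages

**Tiling** (`ihcquant.tiler`). A slide image is partitioned into a
row-major grid of tiles, default 1200 × 800 px, top-left origin, 0-based
indices; edge tiles keep their residual size (padding would inflate
background tallies). The grid is a true partition — every pixel in
exactly one tile — so any pixel-local measurement is tiling-invariant,
and `reassemble ∘ split` is the identity on lossless inputs. JPEG tiles
are accepted (the acquisition format), but tests use PNG so round-trip
assertions are exact.

**Chromogen segmentation** (`ihcquant.chromogen`). Red: full-range
BT.601 YCbCr (the JPEG convention; Y = 0.299R + 0.587G + 0.114B, Cb/Cr
centred at 128), linear brightness/contrast adjustment
`gain·(v−128)+128+offset` about the mid-grey pivot, then a strict
`> threshold` binarization of Cr. Brown: pixels in a brown HSV band are
recoloured toward red and the identical detector is rerun; pixels
already in the red mask are removed (mutual exclusion, red priority),
so red + brown + unstained = total. Counting is a histogram tally of
the binary pattern.

Defaults (all exposed in `SegmentationParams` and as CLI flags/YAML):

| parameter | default | rationale |
|---|---|---|
| `cr_threshold` | 175 | midway between the DAB-brown palette's Cr (≈151) and the red chromogen's (≈204); ≥3 noise SDs from both at the default noise level |
| `contrast_gain`, `brightness_offset` | 1, 0 | Cr separation suffices at defaults; knobs kept for faint stains |
| `brown_hue_band` | hue 5–45 of 255, sat ≥ 60, val ≥ 40 | DAB-brown sits near hue 20; red (~251, wrapping) and haematoxylin (~170) stay outside; the sat/val floors exclude grey and near-black pixels, which have no stable hue |
| `brown_shift_target` | (0, 230, 200) HSV, mode `target` | brown-band pixels are set to a saturated bright red whose Cr (≈218) the threshold always catches. A `mode="offset"` variant adds the triple to each pixel's HSV instead; both interpretations are supported because imaging tools disagree on hue/saturation conventions, and a dim target (e.g. value 50 of 255) would be undetectable on Cr no matter its hue |
| `mutual_exclusion` | on | the two-pass design would otherwise count every red pixel twice |

Boundary convention: strictly-greater thresholding, so boundary-valued
pixels are unstained. Arbitrary but fixed and tested.

**Calibration** (`ihcquant.calibration`). Factors are fitted by the
summed ratio Σpixels/Σcells over the panel — not the mean of per-image
ratios, which would weight sparse images absurdly. The reference count
per image is the mean of the two raters. Integer conversion is
truncation by default; `nearest` is available because reference worked
examples are split between the two conventions, and every value the
tests pin is robust to either. Gland aggregation sums pixels over all
tiles first and converts once; converting per tile and summing can
differ by up to one cell per tile (tested bound).

**The packaged panel** (`data/calibration_table.csv`, 31 images). Six
rows of the printed source table are undelimited digit runs. The
transcription was resolved by exhaustively enumerating digit-splits
consistent with comma-grouping and searching the combinations against
*all* printed column summaries. Two structural facts fall out: the
printed quartiles are Tukey hinges — (x₈+x₉)/2 and (x₂₃+x₂₄)/2 of 31
sorted values — which individually pins several rows (e.g. the red
lower hinge 2217 = (1778+2656)/2 forces all six garbled red values
below 1778), and the row `gland_89_9` is forced to
(11, 9, 909, 273, 297, 26 749) by the T-count medians. The shipped
primary parse reproduces every median and hinge exactly and the B/T
column means to the printed integer; the red mean lands 0.15 % high and
no admissible parse can reach the printed brown mean (best ≈27 113 vs
27 210) — the fitted factors, which are what matter downstream, are
insensitive to this (k_T = 99.7 against the canonical 100). Ambiguous
rows are flagged and carry their alternative parses; a test recomputes
the medians under every combination.

One published value is not supported by the printed table: the Pearson
correlation between red pixels and mean manual B count computes to
0.921, not 0.95; a leave-one-out scan shows 0.955 exactly when the
densest panel image is removed, so the published figure was most likely
computed without it. The package reports the value the full table
yields; the corresponding check is expected to fail and is left failing
rather than patched around. The brown-side correlation (0.917 vs a
published 0.91) and all ICCs (inter-rater 0.994 vs 0.99 with CI
0.987–0.997; manual-vs-digital 0.922/0.917 vs 0.92) reproduce within
rounding.

**Agreement statistics** (`ihcquant.agreement`). ICC variant: ICC(2,1),
two-way random effects, single rater, absolute agreement — the variant
that penalises systematic offsets between methods, which is the
question method comparison asks. It is computed from the ANOVA mean
squares (MSR, MSC, MSE) with the Shrout–Fleiss/McGraw–Wong F-based CI
(Satterthwaite degrees of freedom); the implementation is cross-checked
against `pingouin`'s ICC(A,1) in the test suite. Degenerate inputs:
identical rater columns with subject variance return 1 with a warning;
an all-constant matrix raises. Bland-Altman uses the sample (n−1) SD.
Pearson/Spearman/Mann-Whitney/Kruskal-Wallis delegate to scipy
(two-sided, asymptotic with tie correction) and are verified against
loop-based references to 1e-12; p-values are reported but never used as
pass/fail evidence anywhere in the package.

## The synthetic generator

`ihcquant.synthetic` emulates what the segmentation sees, not
histology: elliptical blobs with per-blob palette jitter (red mean RGB
(200, 45, 60), DAB-brown (120, 80, 45), haematoxylin nuclei
(70, 70, 140) on a pale base — artifact defaults placed in the correct
YCbCr/HSV regions), Gaussian pixel noise (SD 6), and either a white or
a nucleus-scattered background. Default per-tile cell numbers are 128 B
and 272 T — the calibration panel's mean manual counts — at 1200 × 800
px with radius-8 blobs (≈200 px² stained area, between the two
calibrated pixels-per-cell factors). Placement is rejection-sampled
without overlap by default so ground-truth areas are exact per blob; an
overlap mode exists for density-saturation stress tests, and areas
remain exact there too because the renderer records the painted label
map. Rendering is deterministic given the seed (one PCG64 stream).

What it deliberately omits: morphology beyond ellipses, staining
gradients, fixation/sectioning artefacts, chromogen co-localisation,
and scanner optics. Passing tests therefore demonstrate that the
algorithm chain is correct and self-consistent — segmentation recovers
known areas, calibration recovers known factors, the statistics match
references — not that the shipped default threshold is optimal for any
particular laboratory's staining; the calibration step is what adapts
the method to real material.

## Problem sizes and numerical choices

Unit tests run tiles of 48 × 32 to 400 × 300 px and glands of 1–5
tiles; the acceptance script simulates 50 glands of 1–3 tiles at
200 × 140 px with Poisson(10)/Poisson(18) cells per tile, calibrates on
25 and predicts the held-out 25 (typical results: Pearson ≈ 0.99
digital-vs-true, median absolute relative error ≈ 5 %). These sizes
were chosen as the smallest at which the statistical assertions are
stable across seeds. Brute-force per-pixel oracles run on 48 × 32
tiles. All randomness flows from explicit integer seeds; derived seeds
stay below 2³¹.

## Known limitations

- The hue conventions of the original acquisition software are unknown;
  the brown remap triple is configurable but its default is this
  package's own calibration, not a published constant.
- The published cohort-level results (62-gland medians by histological
  grade, clinical correlations) require patient-level data that were
  never published; the statistics operations are provided, the cohort
  numbers are not reproduced.
- Proprietary scanner formats (NDPI pyramids) are out of scope; operate
  on exported PNG/TIFF/JPEG.
- Cell morphology is ignored by design: touching cells are resolved by
  area calibration, not by object detection, so per-cell readouts
  (e.g. size distributions) are outside the model.
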