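# ihcquant

Pixel-based quantification of B and T lymphocytes in whole
double-immunostained minor-salivary-gland biopsy (MSGB) slides.

In primary Sjögren's syndrome the diagnostic biopsy is graded by the
density and composition of its lymphocytic infiltrate, and the
proportion of B cells among infiltrating lymphocytes rises with lesion
severity. Counting B and T cells by hand with a cell-counter tool takes
about 15 minutes per microscope field; `ihcquant` implements the digital
alternative: scan the whole slide, cut it into a systematic mosaic of
~1200 × 800 px tiles, classify every pixel by chromogen colour — red
(alkaline-phosphatase, anti-CD20, B cells) vs brown (DAB, anti-CD3,
T cells) vs haematoxylin background — and convert stained-pixel tallies
into cell counts through calibrated pixels-per-cell factors. The package
is aimed at pathology/rheumatology research groups who want standardised
whole-section B/T quantification from ordinary RGB slide exports, plus
the method-comparison statistics needed to validate it on their own
staining protocol.

## Method

Per tile, a pixel is called **red** when the Cr (red-chrominance)
channel of the full-range BT.601 YCbCr transform,
`Cr = 128 + 0.5R − 0.4187G − 0.0813B`, exceeds a threshold after an
optional brightness/contrast adjustment. **Brown** pixels are found by a
second pass: pixels in a brown HSV band are recoloured to a saturated
red, the identical Cr detector is run again, and pixels already claimed
by the red mask are excluded so no pixel is counted twice.

Pixel tallies become cell counts via summed-ratio conversion factors
fitted on a calibration panel of images with paired manual counts:

    k = Σ pixels / Σ reference cells ,   digital count = ⌊pixels / k⌋

The packaged 31-image panel (two pathologists' manual counts plus pixel
tallies per image) yields k_B ≈ 287 red px/B cell and k_T ≈ 100 brown
px/T cell. Per gland, pixels are summed over all mosaic tiles before a
single conversion, and the headline readout is the B-cell proportion
B/(B+T).

Agreement between counting methods is summarised by ICC(2,1) (two-way
random effects, absolute agreement, from ANOVA mean squares with the
F-based 95 % CI), Bland-Altman bias ± 1.96 SD limits of agreement,
and Pearson/Spearman correlations; Mann-Whitney/Kruskal-Wallis group
comparisons are included for relating gland quantifications to
histological grades.

A synthetic-data module renders double-stained tiles (elliptical
chromogen blobs over white or haematoxylin-like backgrounds, Gaussian
noise) with exact ground-truth counts and areas, so the entire chain is
testable without a slide scanner.

## Worked example

```bash
python examples/03_calibration_panel.py
```

prints

```
calibration panel: 31 images
fitted factors: k_B = 287.0 red px/B cell, k_T = 99.7 brown px/T cell

worked conversions at the canonical rounded factors (287 / 100):
    10,413 px / 287 =    36 cells  (sparse image, red)
   171,921 px / 287 =   599 cells  (dense image, red)
   101,444 px / 100 =  1014 cells  (dense image, brown)
```

i.e. the summed-ratio rule recovers the canonical factors from the
panel, and converting the pixel tallies of three reference micrographs
reproduces their digital counts (36 B cells in a sparse image; 599 B /
1014 T cells in dense, germinal-centre-like images). The other examples
cover tiling (`01`), single-tile segmentation against simulated ground
truth (`02`), agreement statistics (`04` — inter-rater ICC 0.994,
manual-vs-digital ICC 0.92 with near-zero bias) and the calibrated
whole-gland pipeline (`05` — recovers a 34 % true B-cell proportion as
36 %).

The same pipeline is scriptable from the shell:

```bash
ihcquant simulate -o sim/ --n-tiles 4 --seed 1      # synthetic gland
ihcquant quantify sim/ -o out/ --factors 287,100    # per-tile CSV + gland JSON
ihcquant calibrate -o factors.json                  # fit factors on the panel
ihcquant validate -o report/                        # agreement JSON + Bland-Altman CSV
```

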