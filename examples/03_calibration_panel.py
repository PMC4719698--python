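"""Fit pixels-per-cell conversion factors on the packaged calibration panel.

The panel holds 31 double-stained images with manual B/T counts by two
pathologists plus red/brown pixel tallies.  The summed-ratio rule
(sum of pixels / sum of mean manual counts) gives one factor per
chromogen - about 287 red pixels per B cell and 100 brown pixels per
T cell - which then converts any pixel tally into a digital cell count.
"""

from ihcquant import fit_factors, load_calibration_fixture, pixels_to_cells

panel = load_calibration_fixture()
factors = fit_factors(panel)

print(f"calibration panel: {len(panel)} images")
print(f"fitted factors: k_B = {factors.k_b:.1f} red px/B cell, "
      f"k_T = {factors.k_t:.1f} brown px/T cell")

print("\nworked conversions at the canonical rounded factors (287 / 100):")
for pixels, factor, label in [
    (10_413, 287, "sparse image, red"),
    (171_921, 287, "dense image, red"),
    (101_444, 100, "dense image, brown"),
]:
    print(f"  {pixels:>8,} px / {factor} = {pixels_to_cells(pixels, factor):>5} cells  ({label})")
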