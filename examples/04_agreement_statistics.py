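"""Validate the digital counts against the manual reference standard.

Computes, on the packaged calibration panel: the inter-rater ICC of the
two manual counters, the ICC between mean-manual and digital counts,
pixel-vs-manual correlations, and the Bland-Altman bias with its limits
of agreement.  ICC(2,1) near 1 means the two methods agree in absolute
terms, not merely rank the images the same way.
"""

from ihcquant import load_calibration_fixture
from ihcquant.validation import calibration_report

report = calibration_report(load_calibration_fixture())

b = report["inter_rater_b"]
print(f"inter-rater ICC (B cells): {b['icc']:.3f} "
      f"(95% CI {b['icc_ci_low']:.3f}-{b['icc_ci_high']:.3f})")

for cell in ("b", "t"):
    section = report[f"manual_vs_digital_{cell}"]
    print(f"manual vs digital, {cell.upper()} cells: ICC {section['icc']:.3f}, "
          f"bias {section['bias']:+.1f} cells, "
          f"limits of agreement ({section['loa_low']:.1f}, {section['loa_high']:.1f})")

pv = report["pixel_vs_manual"]
print(f"Pearson r: red px vs manual B {pv['pearson_red_vs_b']:.3f}, "
      f"brown px vs manual T {pv['pearson_brown_vs_t']:.3f}")
print("(an ICC ~0.92 with near-zero bias: the digital count is an unbiased "
      "but noisier stand-in for the 15-min manual count)")
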