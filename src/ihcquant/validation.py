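"""End-to-end validation of the digital procedure against manual counts.

Reproduces the published validation workflow on a calibration panel:
inter-rater agreement of the two manual counters, summed-ratio factor
fitting, conversion of pixel tallies to digital counts, and agreement of
digital vs mean-manual counts per cell type.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import agreement
from .calibration import (
    CalibrationImageRecord,
    ConversionFactors,
    fit_factors,
    mean_manual,
    pixels_to_cells,
)


def panel_arrays(records: Sequence[CalibrationImageRecord]) -> dict[str, np.ndarray]:
    """Column vectors of a calibration panel, in record order."""
    return {
        "b_rater1": np.array([r.b_rater1 for r in records], float),
        "b_rater2": np.array([r.b_rater2 for r in records], float),
        "t_rater1": np.array([r.t_rater1 for r in records], float),
        "t_rater2": np.array([r.t_rater2 for r in records], float),
        "red_pixels": np.array([r.red_pixels for r in records], float),
        "brown_pixels": np.array([r.brown_pixels for r in records], float),
        "mean_b": np.array([mean_manual(r, "b") for r in records], float),
        "mean_t": np.array([mean_manual(r, "t") for r in records], float),
    }


def digital_counts(
    records: Sequence[CalibrationImageRecord], factors: ConversionFactors
) -> tuple[np.ndarray, np.ndarray]:
    """Per-image digital (B, T) counts under the given factors."""
    dig_b = np.array(
        [pixels_to_cells(r.red_pixels, factors.k_b, factors.rounding_mode) for r in records],
        float,
    )
    dig_t = np.array(
        [pixels_to_cells(r.brown_pixels, factors.k_t, factors.rounding_mode) for r in records],
        float,
    )
    return dig_b, dig_t


def calibration_report(
    records: Sequence[CalibrationImageRecord],
    factors: ConversionFactors | None = None,
    rounding_mode: str = "floor",
) -> dict:
    """Full agreement/calibration summary of a panel.

    When ``factors`` is None they are fitted from the panel itself by the
    summed-ratio rule.  Returns a plain dict (JSON-serialisable).
    """
    records = list(records)
    cols = panel_arrays(records)
    if factors is None:
        factors = fit_factors(records, rounding_mode)
    dig_b, dig_t = digital_counts(records, factors)

    inter_b = agreement.agreement_report(cols["b_rater1"], cols["b_rater2"])
    inter_t = agreement.agreement_report(cols["t_rater1"], cols["t_rater2"])
    man_dig_b = agreement.agreement_report(cols["mean_b"], dig_b)
    man_dig_t = agreement.agreement_report(cols["mean_t"], dig_t)

    return {
        "n_images": len(records),
        "factors": {
            "k_b": factors.k_b,
            "k_t": factors.k_t,
            "rounding_mode": factors.rounding_mode,
        },
        "pixel_summary": {
            "median_red_pixels": float(np.median(cols["red_pixels"])),
            "median_brown_pixels": float(np.median(cols["brown_pixels"])),
            "mean_red_pixels": float(cols["red_pixels"].mean()),
            "mean_brown_pixels": float(cols["brown_pixels"].mean()),
        },
        "pixel_vs_manual": {
            "pearson_red_vs_b": agreement.pearson_r(cols["red_pixels"], cols["mean_b"]),
            "pearson_brown_vs_t": agreement.pearson_r(cols["brown_pixels"], cols["mean_t"]),
            "spearman_red_vs_b": agreement.spearman_rho(cols["red_pixels"], cols["mean_b"]),
            "spearman_brown_vs_t": agreement.spearman_rho(cols["brown_pixels"], cols["mean_t"]),
        },
        "inter_rater_b": inter_b.to_dict(),
        "inter_rater_t": inter_t.to_dict(),
        "manual_vs_digital_b": man_dig_b.to_dict(),
        "manual_vs_digital_t": man_dig_t.to_dict(),
    }


def bland_altman_table(
    records: Sequence[CalibrationImageRecord], factors: ConversionFactors
) -> pd.DataFrame:
    """Per-image (mean, difference) pairs for Bland-Altman plotting.

    One row per image and cell type; difference is digital minus the
    mean-manual reference.
    """
    dig_b, dig_t = digital_counts(records, factors)
    cols = panel_arrays(records)
    rows = []
    for i, record in enumerate(records):
        for cell, manual, digital in (
            ("b", cols["mean_b"][i], dig_b[i]),
            ("t", cols["mean_t"][i], dig_t[i]),
        ):
            rows.append(
                {
                    "image_id": record.image_id,
                    "cell_type": cell,
                    "manual_mean": manual,
                    "digital": digital,
                    "mean": (manual + digital) / 2.0,
                    "difference": digital - manual,
                }
            )
    return pd.DataFrame(rows)
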