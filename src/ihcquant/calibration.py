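"""Pixel-to-cell calibration and per-gland aggregation.

Stained-pixel tallies are converted to cell counts through summed-ratio
conversion factors fitted on a panel of images with paired manual
reference counts: k = (sum of pixels) / (sum of reference cells), one
factor per chromogen.  The published panel of 31 double-stained images
ships with the package as a CSV fixture (two raters' manual B/T counts
plus red/brown pixel counts per image); the factors it yields are about
287 red pixels per B cell and 100 brown pixels per T cell.

Rows of the printed panel whose digit runs admit more than one reading
are flagged ``ambiguous`` and carry their admissible alternative parses,
so downstream statistics can be checked for robustness to the
transcription.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chromogen import PixelCount

#: micrometres per pixel of the reference scanner setting (20x).
MICRONS_PER_PIXEL = 0.46

_FIXTURE_NAME = "calibration_table.csv"
_PARSE_FIELDS = ("b_rater1", "b_rater2", "red_pixels", "t_rater1", "t_rater2", "brown_pixels")


@dataclass(frozen=True)
class CalibrationImageRecord:
    """One calibration-panel row: manual counts by two raters + pixel tallies."""

    image_id: str
    b_rater1: int
    b_rater2: int
    t_rater1: int
    t_rater2: int
    red_pixels: int
    brown_pixels: int
    ambiguous: bool = False
    alt_parses: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        values = (self.b_rater1, self.b_rater2, self.t_rater1, self.t_rater2,
                  self.red_pixels, self.brown_pixels)
        if min(values) < 0:
            raise ValueError("calibration counts must be non-negative")

    def mean_manual(self, cell_type: str) -> float:
        """Mean of the two raters' counts — the reference standard."""
        return mean_manual(self, cell_type)


@dataclass(frozen=True)
class ConversionFactors:
    """Pixels-per-cell factors with the integer rounding rule."""

    k_b: float = 287.0
    k_t: float = 100.0
    rounding_mode: str = "floor"

    def __post_init__(self) -> None:
        if self.k_b <= 0 or self.k_t <= 0:
            raise ValueError("conversion factors must be positive")
        if self.rounding_mode not in ("floor", "nearest"):
            raise ValueError("rounding_mode must be 'floor' or 'nearest'")


@dataclass(frozen=True)
class GlandQuantification:
    """Whole-gland pixel sums, digital counts and B-cell proportion.

    ``b_proportion``/``t_proportion`` are NaN (undefined) when the gland
    has no digitally counted cells at all.
    """

    gland_id: str
    n_tiles: int
    sum_red_pixels: int
    sum_brown_pixels: int
    sum_total_pixels: int
    digital_b: int
    digital_t: int
    b_proportion: float
    t_proportion: float

    @property
    def proportions_defined(self) -> bool:
        return not math.isnan(self.b_proportion)


@dataclass(frozen=True)
class GlandRecord:
    """Per-gland conventional histology metadata (consumed, never computed)."""

    gland_id: str
    chisholm_grade: str
    tarpley_class: str
    focus_score: float
    germinal_centres: bool

    _CHISHOLM = ("0", "I", "II", "III", "IV")
    _TARPLEY = ("SS-I", "SS-II", "SS-III")

    def __post_init__(self) -> None:
        if self.chisholm_grade not in self._CHISHOLM:
            raise ValueError(f"chisholm_grade must be one of {self._CHISHOLM}")
        if self.tarpley_class not in self._TARPLEY:
            raise ValueError(f"tarpley_class must be one of {self._TARPLEY}")
        if self.focus_score < 0:
            raise ValueError("focus_score must be non-negative")


def mean_manual(record: CalibrationImageRecord, cell_type: str) -> float:
    """Arithmetic mean of the two raters' counts for ``cell_type`` ('b' or 't')."""
    cell_type = cell_type.lower()
    if cell_type == "b":
        return (record.b_rater1 + record.b_rater2) / 2.0
    if cell_type == "t":
        return (record.t_rater1 + record.t_rater2) / 2.0
    raise ValueError("cell_type must be 'b' or 't'")


def fit_conversion_factor(
    pixel_counts: Sequence[float], manual_counts: Sequence[float]
) -> float:
    """Summed-ratio pixels-per-cell factor: sum(pixels) / sum(cells).

    The two sums run over the same panel of images; the result is an
    unrounded float.  Raises on an empty panel or a zero cell sum.
    """
    pixels = np.asarray(pixel_counts, dtype=np.float64)
    cells = np.asarray(manual_counts, dtype=np.float64)
    if pixels.size == 0 or pixels.shape != cells.shape:
        raise ValueError("pixel and manual counts must be equal-length, non-empty")
    cell_sum = cells.sum()
    if cell_sum <= 0:
        raise ValueError("sum of manual counts must be positive")
    return float(pixels.sum() / cell_sum)


def fit_factors(
    records: Iterable[CalibrationImageRecord], rounding_mode: str = "floor"
) -> ConversionFactors:
    """Fit both chromogen factors from a calibration panel."""
    records = list(records)
    k_b = fit_conversion_factor(
        [r.red_pixels for r in records], [mean_manual(r, "b") for r in records]
    )
    k_t = fit_conversion_factor(
        [r.brown_pixels for r in records], [mean_manual(r, "t") for r in records]
    )
    return ConversionFactors(k_b=k_b, k_t=k_t, rounding_mode=rounding_mode)


def pixels_to_cells(pixels: float, factor: float, rounding_mode: str = "floor") -> int:
    """Digital cell count from a stained-pixel tally.

    ``floor`` truncates (10,413 px / 287 -> 36), ``nearest`` rounds
    half away from zero.
    """
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    if pixels < 0:
        raise ValueError("pixel count must be non-negative")
    ratio = pixels / factor
    if rounding_mode == "floor":
        return int(math.floor(ratio))
    if rounding_mode == "nearest":
        return int(math.floor(ratio + 0.5))
    raise ValueError("rounding_mode must be 'floor' or 'nearest'")


def aggregate_gland(
    tile_counts: Sequence[PixelCount],
    factors: ConversionFactors,
    gland_id: str = "",
) -> GlandQuantification:
    """Whole-gland quantification: sum pixels over tiles, then convert once.

    Summing before the integer conversion avoids accumulating per-tile
    truncation error (the two orders differ by at most one cell per
    tile).  A gland with no stained pixels gets NaN proportions rather
    than a 0/0.
    """
    if len(tile_counts) == 0:
        raise ValueError("at least one tile is required")
    sum_red = int(sum(c.red_pixels for c in tile_counts))
    sum_brown = int(sum(c.brown_pixels for c in tile_counts))
    sum_total = int(sum(c.total_pixels for c in tile_counts))
    digital_b = pixels_to_cells(sum_red, factors.k_b, factors.rounding_mode)
    digital_t = pixels_to_cells(sum_brown, factors.k_t, factors.rounding_mode)
    denom = digital_b + digital_t
    if denom > 0:
        b_prop = digital_b / denom
        t_prop = digital_t / denom
    else:
        b_prop = t_prop = float("nan")
    return GlandQuantification(
        gland_id=gland_id,
        n_tiles=len(tile_counts),
        sum_red_pixels=sum_red,
        sum_brown_pixels=sum_brown,
        sum_total_pixels=sum_total,
        digital_b=digital_b,
        digital_t=digital_t,
        b_proportion=b_prop,
        t_proportion=t_prop,
    )


def tissue_area_mm2(tissue_pixels: int, microns_per_pixel: float = MICRONS_PER_PIXEL) -> float:
    """Convenience pixel-count -> mm^2 conversion at the scanner resolution.

    Provided for orientation only; the reference gland areas were
    measured with an unspecified procedure, so this helper is not a
    validated reproduction of them.
    """
    return tissue_pixels * (microns_per_pixel / 1000.0) ** 2


# ---------------------------------------------------------------------------
# Fixture and CSV IO


def _records_from_frame(df: pd.DataFrame) -> list[CalibrationImageRecord]:
    records = []
    for row in df.itertuples(index=False):
        alts: tuple[tuple[int, ...], ...] = ()
        raw_alt = getattr(row, "alt_parse", "") or ""
        if isinstance(raw_alt, str) and raw_alt.strip():
            alts = tuple(
                tuple(int(x) for x in chunk.split("|")) for chunk in raw_alt.split(";")
            )
        records.append(
            CalibrationImageRecord(
                image_id=str(row.image_id),
                b_rater1=int(row.b_rater1),
                b_rater2=int(row.b_rater2),
                red_pixels=int(row.red_pixels),
                t_rater1=int(row.t_rater1),
                t_rater2=int(row.t_rater2),
                brown_pixels=int(row.brown_pixels),
                ambiguous=bool(getattr(row, "ambiguous", False)),
                alt_parses=alts,
            )
        )
    return records


def load_calibration_table(path: str | Path) -> list[CalibrationImageRecord]:
    """Read a calibration panel CSV (fixture schema) into records."""
    df = pd.read_csv(path, keep_default_na=False)
    required = {"image_id", *_PARSE_FIELDS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    if "ambiguous" in df.columns:
        df["ambiguous"] = df["ambiguous"].astype(str).str.lower().isin(("true", "1"))
    return _records_from_frame(df)


def load_calibration_fixture() -> list[CalibrationImageRecord]:
    """The packaged 31-image calibration panel."""
    with resources.as_file(resources.files("ihcquant.data") / _FIXTURE_NAME) as path:
        records = load_calibration_table(path)
    if len(records) != 31:
        raise RuntimeError("packaged calibration fixture must contain 31 records")
    return records


def apply_parse(
    record: CalibrationImageRecord, parse: Sequence[int]
) -> CalibrationImageRecord:
    """A copy of ``record`` with the six count fields replaced by ``parse``.

    Field order matches the fixture columns: b_rater1, b_rater2,
    red_pixels, t_rater1, t_rater2, brown_pixels.
    """
    if len(parse) != 6:
        raise ValueError("a parse has exactly six fields")
    kwargs = dict(zip(_PARSE_FIELDS, (int(v) for v in parse)))
    return CalibrationImageRecord(
        image_id=record.image_id,
        ambiguous=record.ambiguous,
        alt_parses=record.alt_parses,
        **kwargs,
    )


def records_to_frame(records: Iterable[CalibrationImageRecord]) -> pd.DataFrame:
    rows = [
        {
            "image_id": r.image_id,
            "b_rater1": r.b_rater1,
            "b_rater2": r.b_rater2,
            "red_pixels": r.red_pixels,
            "t_rater1": r.t_rater1,
            "t_rater2": r.t_rater2,
            "brown_pixels": r.brown_pixels,
            "mean_manual_b": mean_manual(r, "b"),
            "mean_manual_t": mean_manual(r, "t"),
            "ambiguous": r.ambiguous,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def load_gland_metadata(path: str | Path) -> list[GlandRecord]:
    """Read per-gland histology metadata (Chisholm, Tarpley, FS, GC flag)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GlandRecord(
                gland_id=str(row.gland_id),
                chisholm_grade=str(row.chisholm_grade),
                tarpley_class=str(row.tarpley_class),
                focus_score=float(row.focus_score),
                germinal_centres=bool(row.germinal_centres),
            )
        )
    return records
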