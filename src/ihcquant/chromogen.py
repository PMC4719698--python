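"""Dual-chromogen pixel classification for red/brown double stains.

CD20+ B cells carry a red chromogen (alkaline-phosphatase red), CD3+
T cells a brown one (DAB), over a bluish haematoxylin counterstain.  Red
is segmented on the Cr (red-chrominance) channel of a full-range BT.601
YCbCr transform: after an optional brightness/contrast adjustment the
channel is thresholded into a binary stained/unstained pattern.  Brown is
segmented by first remapping brown-hued pixels to a saturated red in HSV
space and then running the identical red detector, so a single
chrominance cutoff serves both chromogens.

The remap target and threshold are configurable because different
staining batches (and different HSV conventions in imaging software)
place the chromogens at different coordinates; the defaults are
calibrated against the synthetic chromogen palettes in
:mod:`ihcquant.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import yaml
from skimage import color as skcolor

# Full-range BT.601 (the JPEG convention): Y in [0,255], Cb/Cr centred at 128.
_YCBCR_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_YCBCR_OFFSET = np.array([0.0, 128.0, 128.0])


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the two-pass chromogen classifier.

    cr_threshold
        8-bit Cr cutoff; pixels strictly above it count as stained.
    contrast_gain, brightness_offset
        Linear adjustment ``gain*(v-128)+128+offset`` applied to the Cr
        channel before thresholding.
    brown_shift_target
        (hue, saturation, value) triple on 8-bit scales (hue wheel 0-255
        with red at 0) used to recolour brown-band pixels.
    brown_shift_mode
        ``"target"`` sets brown-band pixels to the triple; ``"offset"``
        adds the triple to their HSV coordinates (hue modular,
        saturation/value clipped).
    brown_hue_band, brown_sat_min, brown_val_min
        Membership test for "brown" in HSV (8-bit scales).
    mutual_exclusion
        Remove red-detected pixels from the brown mask so no pixel is
        counted twice (red has priority).
    """

    cr_threshold: float = 175.0
    contrast_gain: float = 1.0
    brightness_offset: float = 0.0
    brown_shift_target: tuple[float, float, float] = (0.0, 230.0, 200.0)
    brown_shift_mode: str = "target"
    brown_hue_band: tuple[float, float] = (5.0, 45.0)
    brown_sat_min: float = 60.0
    brown_val_min: float = 40.0
    mutual_exclusion: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.cr_threshold <= 255:
            raise ValueError("cr_threshold must lie in [0, 255]")
        if self.contrast_gain <= 0:
            raise ValueError("contrast_gain must be positive")
        if self.brown_shift_mode not in ("target", "offset"):
            raise ValueError("brown_shift_mode must be 'target' or 'offset'")
        if not all(0 <= c <= 255 for c in self.brown_shift_target):
            raise ValueError("brown_shift_target components must lie in [0, 255]")

    @classmethod
    def from_yaml(cls, path) -> "SegmentationParams":
        raw = yaml.safe_load(open(path)) or {}
        for key in ("brown_shift_target", "brown_hue_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "SegmentationParams":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass(frozen=True)
class PixelCount:
    """Per-tile tallies of stained and total pixels."""

    red_pixels: int
    brown_pixels: int
    total_pixels: int
    tile_id: str = ""

    def __post_init__(self) -> None:
        if min(self.red_pixels, self.brown_pixels, self.total_pixels) < 0:
            raise ValueError("pixel counts must be non-negative")


def _as_rgb(tile: np.ndarray) -> np.ndarray:
    arr = np.asarray(tile)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB tile")
    return arr.astype(np.float64)


def rgb_to_ycbcr(tile: np.ndarray) -> np.ndarray:
    """Full-range BT.601 YCbCr transform of an 8-bit RGB tile.

    Y = 0.299R + 0.587G + 0.114B; Cb/Cr are chrominance channels centred
    at 128.  Output is clipped to [0, 255] and returned as float HxWx3.
    """
    rgb = _as_rgb(tile)
    ycbcr = rgb @ _YCBCR_MATRIX.T + _YCBCR_OFFSET
    return np.clip(ycbcr, 0.0, 255.0)


def adjust_brightness_contrast(
    channel: np.ndarray, gain: float = 1.0, offset: float = 0.0
) -> np.ndarray:
    """Linear contrast stretch about the mid-grey pivot, clipped to [0, 255]."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    out = gain * (np.asarray(channel, dtype=np.float64) - 128.0) + 128.0 + offset
    return np.clip(out, 0.0, 255.0)


def threshold_to_binary(channel: np.ndarray, threshold: float) -> np.ndarray:
    """Binary stained mask: True where the channel is strictly above threshold."""
    return np.asarray(channel, dtype=np.float64) > threshold


def detect_red(tile: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Red-chromogen mask via Cr-channel binarization."""
    params = params or SegmentationParams()
    cr = rgb_to_ycbcr(tile)[..., 2]
    adjusted = adjust_brightness_contrast(cr, params.contrast_gain, params.brightness_offset)
    return threshold_to_binary(adjusted, params.cr_threshold)


def brown_band_mask(tile: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Pixels whose HSV coordinates fall in the configured brown band."""
    params = params or SegmentationParams()
    hsv = skcolor.rgb2hsv(_as_rgb(tile) / 255.0)
    hue = hsv[..., 0] * 255.0
    sat = hsv[..., 1] * 255.0
    val = hsv[..., 2] * 255.0
    lo, hi = params.brown_hue_band
    in_band = (hue >= lo) & (hue <= hi) if lo <= hi else (hue >= lo) | (hue <= hi)
    return in_band & (sat >= params.brown_sat_min) & (val >= params.brown_val_min)


def shift_brown_to_red(tile: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Recolour brown-band pixels toward red; all other pixels pass through.

    Grey pixels (zero saturation) and already-red pixels lie outside the
    brown band and are returned byte-identical.
    """
    params = params or SegmentationParams()
    rgb = np.asarray(tile)
    band = brown_band_mask(rgb, params)
    if not band.any():
        return rgb.copy()
    out = rgb.copy()
    h, s, v = params.brown_shift_target
    if params.brown_shift_mode == "target":
        target_rgb = skcolor.hsv2rgb(np.array([[[h / 255.0, s / 255.0, v / 255.0]]])) * 255.0
        out[band] = np.clip(np.round(target_rgb[0, 0]), 0, 255).astype(out.dtype)
    else:  # offset
        hsv = skcolor.rgb2hsv(_as_rgb(rgb) / 255.0)
        sel = hsv[band]
        sel[:, 0] = np.mod(sel[:, 0] + h / 255.0, 1.0)
        sel[:, 1] = np.clip(sel[:, 1] + s / 255.0, 0.0, 1.0)
        sel[:, 2] = np.clip(sel[:, 2] + v / 255.0, 0.0, 1.0)
        out[band] = np.clip(np.round(skcolor.hsv2rgb(sel[None, :, :])[0] * 255.0), 0, 255).astype(
            out.dtype
        )
    return out


def detect_brown(tile: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Brown-chromogen mask: hue-shift then the same red detector.

    With ``mutual_exclusion`` on (default), pixels already claimed by
    :func:`detect_red` are removed so red and brown masks are disjoint.
    """
    params = params or SegmentationParams()
    mask = detect_red(shift_brown_to_red(tile, params), params)
    if params.mutual_exclusion:
        mask &= ~detect_red(tile, params)
    return mask


def count_mask(mask: np.ndarray) -> int:
    """Histogram tally of stained ("black") pixels in a binary pattern."""
    return int(np.count_nonzero(np.asarray(mask, dtype=bool)))


def quantify_tile(
    tile: np.ndarray, params: SegmentationParams | None = None, tile_id: str = ""
) -> PixelCount:
    """Red/brown/total pixel counts for one tile."""
    params = params or SegmentationParams()
    arr = np.asarray(tile)
    return PixelCount(
        red_pixels=count_mask(detect_red(arr, params)),
        brown_pixels=count_mask(detect_brown(arr, params)),
        total_pixels=int(arr.shape[0] * arr.shape[1]),
        tile_id=tile_id,
    )


def quantify_tiles(
    tiles: Iterable[tuple[str, np.ndarray]], params: SegmentationParams | None = None
) -> list[PixelCount]:
    """Quantify a sequence of (tile_id, pixels) pairs."""
    params = params or SegmentationParams()
    return [quantify_tile(pixels, params, tile_id) for tile_id, pixels in tiles]
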