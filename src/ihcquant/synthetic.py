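"""Synthetic double-stained IHC tiles with exact ground truth.

Every other module is testable without any real slide: tiles carry
red-chromogen blobs (B cells), DAB-brown blobs (T cells) and either a
plain white background or a haematoxylin-like counterstain of bluish
nuclei, with Gaussian pixel noise on top.  Cells are drawn as
axis-aligned ellipses (lymphocytes are round; at 0.46 um/px a lymphocyte
spans roughly 15 px) whose rasterised pixel support is recorded, so the
true stained area is exact even when blobs overlap.

Default per-tile cell numbers match the calibration panel's mean manual
counts (128 B, 272 T per 1200 x 800 image); palettes are artifact
defaults chosen to land in the chromogen regions of YCbCr/HSV space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

RGB = tuple[float, float, float]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the tile simulator (see module docstring for defaults)."""

    tile_width: int = 1200
    tile_height: int = 800
    n_b_cells: int = 128
    n_t_cells: int = 272
    cell_radius_mean: float = 8.0
    cell_radius_sd: float = 1.5
    red_palette_mean: RGB = (200.0, 45.0, 60.0)
    red_palette_sd: float = 10.0
    brown_palette_mean: RGB = (120.0, 80.0, 45.0)
    brown_palette_sd: float = 10.0
    background_mode: str = "white"
    counterstain_density: float = 0.15
    overlap_allowed: bool = False
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_width < 1 or self.tile_height < 1:
            raise ValueError("tile dimensions must be positive")
        if self.n_b_cells < 0 or self.n_t_cells < 0:
            raise ValueError("cell counts must be non-negative")
        if self.cell_radius_mean <= 0 or self.cell_radius_sd < 0:
            raise ValueError("radii must be positive")
        for palette in (self.red_palette_mean, self.brown_palette_mean):
            if not all(0 <= c <= 255 for c in palette):
                raise ValueError("palette means must lie in [0, 255]")
        if self.background_mode not in ("white", "haematoxylin"):
            raise ValueError("background_mode must be 'white' or 'haematoxylin'")
        if not 0 <= self.counterstain_density <= 1:
            raise ValueError("counterstain_density must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def with_overrides(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Blob:
    cell_type: str  # "b" or "t"
    cx: int
    cy: int
    rx: float
    ry: float


@dataclass(frozen=True)
class GroundTruth:
    """True cell counts and stained pixel areas behind one rendered tile."""

    b_count: int
    t_count: int
    b_area_px: int
    t_area_px: int
    blobs: tuple[Blob, ...]
    seed: int


_WHITE_BG = np.array([248.0, 248.0, 248.0])
_HAEMA_BASE = np.array([226.0, 228.0, 238.0])
_HAEMA_NUCLEUS = np.array([70.0, 70.0, 140.0])


def _ellipse_mask(h: int, w: int, cx: int, cy: int, rx: float, ry: float) -> np.ndarray:
    y0 = max(0, int(np.floor(cy - ry)))
    y1 = min(h, int(np.ceil(cy + ry)) + 1)
    x0 = max(0, int(np.floor(cx - rx)))
    x1 = min(w, int(np.ceil(cx + rx)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    full = np.zeros((h, w), dtype=bool)
    full[y0:y1, x0:x1] = inside
    return full


def _place_blobs(
    rng: np.random.Generator,
    n: int,
    cell_type: str,
    params: SimulationParams,
    occupied: list[tuple[int, int, float]],
) -> list[Blob]:
    """Sample blob centres/radii; rejection-sample against bounding circles
    when overlap is disallowed."""
    h, w = params.tile_height, params.tile_width
    blobs: list[Blob] = []
    max_attempts = 200 * n + 1000
    attempts = 0
    while len(blobs) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping {cell_type!r} blobs in a "
                f"{w}x{h} tile after {max_attempts} attempts"
            )
        attempts += 1
        rx = max(1.0, rng.normal(params.cell_radius_mean, params.cell_radius_sd))
        ry = max(1.0, rng.normal(params.cell_radius_mean, params.cell_radius_sd))
        r = max(rx, ry)
        margin = int(np.ceil(r))
        if 2 * margin >= w or 2 * margin >= h:
            raise RuntimeError(f"blob radius {r:.1f} does not fit a {w}x{h} tile")
        cx = int(rng.integers(margin, w - margin))
        cy = int(rng.integers(margin, h - margin))
        if not params.overlap_allowed:
            if any((cx - ox) ** 2 + (cy - oy) ** 2 < (r + orad) ** 2 for ox, oy, orad in occupied):
                continue
            occupied.append((cx, cy, r))
        blobs.append(Blob(cell_type, cx, cy, rx, ry))
    return blobs


def render_tile(params: SimulationParams | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Render one tile; deterministic for a fixed ``params.seed``.

    Returns the uint8 RGB tile and a :class:`GroundTruth` whose areas are
    the exact pixel supports painted for each cell class (last-painted
    wins where blobs overlap).
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    h, w = params.tile_height, params.tile_width

    img = np.empty((h, w, 3), dtype=np.float64)
    if params.background_mode == "white":
        img[:] = _WHITE_BG
    else:
        img[:] = _HAEMA_BASE
        # scatter bluish nuclei until the requested area fraction is covered
        target = params.counterstain_density * h * w
        covered = np.zeros((h, w), dtype=bool)
        while covered.sum() < target:
            r = max(1.0, rng.normal(4.0, 1.0))
            cx = int(rng.integers(0, w))
            cy = int(rng.integers(0, h))
            m = _ellipse_mask(h, w, cx, cy, r, r)
            covered |= m
            img[m] = np.clip(_HAEMA_NUCLEUS + rng.normal(0.0, 8.0, size=3), 0, 255)

    occupied: list[tuple[int, int, float]] = []
    b_blobs = _place_blobs(rng, params.n_b_cells, "b", params, occupied)
    t_blobs = _place_blobs(rng, params.n_t_cells, "t", params, occupied)

    label = np.zeros((h, w), dtype=np.uint8)  # 0 bg, 1 B, 2 T
    for blob in b_blobs + t_blobs:
        m = _ellipse_mask(h, w, blob.cx, blob.cy, blob.rx, blob.ry)
        mean = params.red_palette_mean if blob.cell_type == "b" else params.brown_palette_mean
        sd = params.red_palette_sd if blob.cell_type == "b" else params.brown_palette_sd
        colour = np.clip(np.asarray(mean) + rng.normal(0.0, sd, size=3), 0, 255)
        img[m] = colour
        label[m] = 1 if blob.cell_type == "b" else 2

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    tile = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        b_count=params.n_b_cells,
        t_count=params.n_t_cells,
        b_area_px=int((label == 1).sum()),
        t_area_px=int((label == 2).sum()),
        blobs=tuple(b_blobs + t_blobs),
        seed=params.seed,
    )
    return tile, truth


DensityProfile = Callable[[np.random.Generator, int], tuple[int, int]] | Sequence[tuple[int, int]]


def render_gland(
    n_tiles: int,
    density_profile: DensityProfile,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[GroundTruth]]:
    """Render a multi-tile gland with heterogeneous per-tile densities.

    ``density_profile`` is either a sequence of (n_b, n_t) pairs of
    length ``n_tiles`` or a callable ``(rng, tile_index) -> (n_b, n_t)``;
    zero pairs give the empty fragments real mosaics contain (fat,
    empty glass).  Reproducible for a fixed ``seed``.
    """
    if n_tiles < 1:
        raise ValueError("a gland has at least one tile")
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    tiles: list[np.ndarray] = []
    truths: list[GroundTruth] = []
    for i in range(n_tiles):
        if callable(density_profile):
            n_b, n_t = density_profile(rng, i)
        else:
            n_b, n_t = density_profile[i]
        tile_seed = int(rng.integers(0, 2**31 - 1))
        tile_params = params.with_overrides(n_b_cells=int(n_b), n_t_cells=int(n_t), seed=tile_seed)
        tile, truth = render_tile(tile_params)
        tiles.append(tile)
        truths.append(truth)
    return tiles, truths
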