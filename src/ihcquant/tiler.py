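"""Non-overlapping tile mosaics of whole-slide images.

A scanned gland section is processed as a systematic grid of fixed-size
fragments (nominally 1200 x 800 px).  The grid is a partition: every slide
pixel belongs to exactly one tile, edge tiles keep their residual size
rather than being padded (padding would inflate background-pixel tallies),
and reassembly is pixel-exact on lossless inputs.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

DEFAULT_TILE_WIDTH = 1200
DEFAULT_TILE_HEIGHT = 800

_TILE_NAME_RE = re.compile(r"^(?P<gland>.+)_(?P<index>\d+)\.(?P<ext>png|jpe?g|tiff?)$", re.I)


@dataclass(frozen=True)
class TileGrid:
    """Geometry of a slide mosaic (row-major, 0-based, top-left origin)."""

    slide_width: int
    slide_height: int
    tile_width: int = DEFAULT_TILE_WIDTH
    tile_height: int = DEFAULT_TILE_HEIGHT
    n_rows: int = field(init=False)
    n_cols: int = field(init=False)

    def __post_init__(self) -> None:
        for name in ("slide_width", "slide_height", "tile_width", "tile_height"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        object.__setattr__(self, "n_rows", math.ceil(self.slide_height / self.tile_height))
        object.__setattr__(self, "n_cols", math.ceil(self.slide_width / self.tile_width))

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def cell_box(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) pixel box of a grid cell, clipped to the slide."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"grid cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        x0 = col * self.tile_width
        y0 = row * self.tile_height
        return x0, y0, min(x0 + self.tile_width, self.slide_width), min(y0 + self.tile_height, self.slide_height)


@dataclass
class Tile:
    """One 8-bit RGB mosaic fragment and its position in the grid."""

    pixels: np.ndarray
    row_index: int
    col_index: int
    x_offset: int
    y_offset: int
    tile_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("tile pixels must be an HxWx3 RGB array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def plan_grid(
    slide_width: int,
    slide_height: int,
    tile_width: int = DEFAULT_TILE_WIDTH,
    tile_height: int = DEFAULT_TILE_HEIGHT,
) -> TileGrid:
    """Plan a systematic, non-overlapping mosaic covering the whole slide."""
    return TileGrid(slide_width, slide_height, tile_width, tile_height)


def split(slide_image: np.ndarray, grid: TileGrid) -> list[Tile]:
    """Split a slide image into row-major tiles partitioning it exactly.

    Raises ``ValueError`` when the image dimensions do not match the grid.
    """
    img = np.asarray(slide_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("slide image must be HxWx3 RGB")
    h, w = img.shape[:2]
    if (w, h) != (grid.slide_width, grid.slide_height):
        raise ValueError(
            f"image is {w}x{h} but grid expects {grid.slide_width}x{grid.slide_height}"
        )
    tiles = []
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            x0, y0, x1, y1 = grid.cell_box(row, col)
            tiles.append(
                Tile(
                    pixels=img[y0:y1, x0:x1].copy(),
                    row_index=row,
                    col_index=col,
                    x_offset=x0,
                    y_offset=y0,
                    tile_id=f"tile_{row * grid.n_cols + col}",
                )
            )
    return tiles


def reassemble(tiles: Iterable[Tile], grid: TileGrid) -> np.ndarray:
    """Pixel-exact inverse of :func:`split` given one tile per grid cell.

    Order-independent: placement uses each tile's grid indices.  Missing or
    duplicated cells raise ``ValueError``.
    """
    tiles = list(tiles)
    if len(tiles) != grid.n_tiles:
        raise ValueError(f"expected {grid.n_tiles} tiles, got {len(tiles)}")
    out = np.zeros((grid.slide_height, grid.slide_width, 3), dtype=np.uint8)
    seen: set[tuple[int, int]] = set()
    for tile in tiles:
        key = (tile.row_index, tile.col_index)
        if key in seen:
            raise ValueError(f"duplicate tile for grid cell {key}")
        seen.add(key)
        x0, y0, x1, y1 = grid.cell_box(*key)
        if tile.pixels.shape[:2] != (y1 - y0, x1 - x0):
            raise ValueError(
                f"tile at {key} is {tile.pixels.shape[:2]}, cell needs {(y1 - y0, x1 - x0)}"
            )
        out[y0:y1, x0:x1] = tile.pixels
    return out


# ---------------------------------------------------------------------------
# File-level interface


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an 8-bit RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)


def write_mosaic(
    slide_image: np.ndarray,
    out_dir: str | Path,
    gland_id: str,
    tile_width: int = DEFAULT_TILE_WIDTH,
    tile_height: int = DEFAULT_TILE_HEIGHT,
    fmt: str = "png",
) -> Path:
    """Write tiles named ``<gland_id>_<n>.<fmt>`` plus a JSON grid manifest.

    Returns the manifest path.  Tile numbering is row-major from 0.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h, w = np.asarray(slide_image).shape[:2]
    grid = plan_grid(w, h, tile_width, tile_height)
    entries = []
    for n, tile in enumerate(split(slide_image, grid)):
        name = f"{gland_id}_{n}.{fmt}"
        save_image(out_dir / name, tile.pixels)
        entries.append({"file": name, "row": tile.row_index, "col": tile.col_index})
    manifest = {
        "gland_id": gland_id,
        "slide_width": grid.slide_width,
        "slide_height": grid.slide_height,
        "tile_width": grid.tile_width,
        "tile_height": grid.tile_height,
        "tiles": entries,
    }
    manifest_path = out_dir / f"{gland_id}_grid.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_mosaic(manifest_path: str | Path) -> tuple[list[Tile], TileGrid]:
    """Load tiles and grid from a manifest written by :func:`write_mosaic`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    grid = TileGrid(
        manifest["slide_width"],
        manifest["slide_height"],
        manifest["tile_width"],
        manifest["tile_height"],
    )
    tiles = []
    for entry in manifest["tiles"]:
        x0, y0, _, _ = grid.cell_box(entry["row"], entry["col"])
        tiles.append(
            Tile(
                pixels=load_image(manifest_path.parent / entry["file"]),
                row_index=entry["row"],
                col_index=entry["col"],
                x_offset=x0,
                y_offset=y0,
                tile_id=Path(entry["file"]).stem,
            )
        )
    return tiles, grid


def scan_tile_directory(directory: str | Path) -> list[tuple[str, Path]]:
    """Find pre-cut tiles named ``<gland>_<n>.<ext>``, ordered by index.

    Directory input implies the fragments are already a non-overlapping
    mosaic; no geometry is reconstructed.
    """
    directory = Path(directory)
    found: list[tuple[int, str, Path]] = []
    for path in sorted(directory.iterdir()):
        m = _TILE_NAME_RE.match(path.name)
        if m:
            found.append((int(m.group("index")), path.stem, path))
    found.sort(key=lambda item: item[0])
    return [(stem, path) for _, stem, path in found]
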