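"""Split a slide image into a systematic tile mosaic and reassemble it.

Builds a small synthetic slide, cuts it into non-overlapping tiles the
way a whole-slide scan is divided into ~1200x800 px fragments, and
shows that the mosaic is a partition (areas sum exactly) and that
reassembly is pixel-exact.
"""

import numpy as np

from ihcquant import plan_grid, reassemble, split

rng = np.random.default_rng(0)
slide = rng.integers(0, 256, size=(900, 1300, 3), dtype=np.uint8)

grid = plan_grid(slide_width=1300, slide_height=900, tile_width=1200, tile_height=800)
tiles = split(slide, grid)

print(f"slide 1300x900 px -> {grid.n_rows} rows x {grid.n_cols} cols = {grid.n_tiles} tiles")
for t in tiles:
    print(f"  tile ({t.row_index},{t.col_index}) at ({t.x_offset},{t.y_offset}): "
          f"{t.shape[1]}x{t.shape[0]} px")

total = sum(t.pixels.shape[0] * t.pixels.shape[1] for t in tiles)
print(f"tile areas sum to {total} px = slide area {1300 * 900} px (partition, no overlap)")

restored = reassemble(tiles, grid)
print(f"reassemble(split(slide)) identical to slide: {bool((restored == slide).all())}")
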