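"""Tile-mosaic stitching: align overlapping 3D tiles by phase correlation and
fuse them onto one macrosection canvas.

Pairwise offsets between grid-adjacent tiles are estimated by 3D phase
correlation on a reference channel (default: the sum of all channels), with
the cyclic ambiguity resolved by scoring all wrap candidates with normalized
cross-correlation (NCC) in the implied overlap.  Pairs whose best NCC falls
below a threshold fall back to the nominal grid offset — phase correlation is
unreliable on near-empty tiles (e.g. corners outside the tissue), and the
grid prior is the honest alternative.  Global tile positions follow from
least squares on the pairwise offset graph, anchored at the first tile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .core import MacrosectionStack, VoxelGrid


@dataclass
class TileLayout:
    """Rectangular acquisition grid of overlapping tiles."""

    rows: int
    cols: int
    overlap: float = 0.1
    order: str = "raster"  # raster (row-major) or serpentine

    def __post_init__(self) -> None:
        n = self.rows * self.cols
        if not 1 <= n <= 1000:
            raise ValueError(f"grid of {n} tiles outside the supported 1..1000")
        if not 0.0 < self.overlap <= 0.5:
            raise ValueError("overlap fraction must be in (0, 0.5]")
        if self.order not in ("raster", "serpentine"):
            raise ValueError(f"unknown acquisition order {self.order!r}")

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    def index(self, r: int, c: int) -> int:
        """Linear index of grid position (r, c) in acquisition order."""
        if self.order == "serpentine" and r % 2 == 1:
            c = self.cols - 1 - c
        return r * self.cols + c

    def grid_positions(self):
        """(r, c) for each linear acquisition index."""
        out = [None] * self.n_tiles
        for r in range(self.rows):
            for c in range(self.cols):
                out[self.index(r, c)] = (r, c)
        return out


def tile_size_for_layout(layout: TileLayout, shape_yx) -> tuple[int, int]:
    """Tile (height, width) so the grid covers ``shape_yx`` at the nominal overlap."""
    out = []
    for n, full in zip((layout.rows, layout.cols), shape_yx):
        eff = n - (n - 1) * layout.overlap
        out.append(min(full, math.ceil(full / eff)))
    return tuple(out)


def nominal_tile_origins(layout: TileLayout, shape_yx):
    """Nominal (y0, x0) per tile, in acquisition order."""
    th, tw = tile_size_for_layout(layout, shape_yx)
    origins = [None] * layout.n_tiles
    for r in range(layout.rows):
        y0 = min(round(r * th * (1 - layout.overlap)), shape_yx[0] - th)
        for c in range(layout.cols):
            x0 = min(round(c * tw * (1 - layout.overlap)), shape_yx[1] - tw)
            origins[layout.index(r, c)] = (int(y0), int(x0))
    return origins


def _reference_image(tile: VoxelGrid, reference_channel: str) -> np.ndarray:
    if reference_channel == "sum":
        return tile.channel_sum()
    return tile.channel(reference_channel).astype(np.float32)


def _ncc_at_offset(a: np.ndarray, b: np.ndarray, offset) -> float:
    """NCC between a and b in the overlap implied by p_b - p_a = offset."""
    sl_a, sl_b = [], []
    for ax in range(3):
        o = int(round(offset[ax]))
        lo = max(0, o)
        hi = min(a.shape[ax], b.shape[ax] + o)
        if hi - lo < 2:
            return -np.inf
        sl_a.append(slice(lo, hi))
        sl_b.append(slice(lo - o, hi - o))
    x = a[tuple(sl_a)].ravel().astype(np.float64)
    y = b[tuple(sl_b)].ravel().astype(np.float64)
    if x.size < 32:
        return -np.inf
    x -= x.mean()
    y -= y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)


def _pairwise_offset(a, b, nominal, subpixel=False):
    """Offset p_b - p_a between two overlapping tiles.

    Returns (offset, ncc score).  The phase-correlation peak is cyclic; every
    per-axis wrap candidate is scored by NCC and the best is kept.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw, _, _ = phase_cross_correlation(
            a, b, upsample_factor=10 if subpixel else 1, normalization="phase"
        )
    raw = np.asarray(raw, dtype=float)
    best = (np.asarray(nominal, dtype=float), -np.inf)
    cands = []
    for ax in range(3):
        n = a.shape[ax]
        cands.append({raw[ax], raw[ax] - n, raw[ax] + n})
    for cz in cands[0]:
        for cy in cands[1]:
            for cx in cands[2]:
                off = np.array([cz, cy, cx])
                score = _ncc_at_offset(a, b, np.round(off))
                if score > best[1]:
                    best = (off, score)
    if subpixel:
        return best
    # the phase peak can be biased by a voxel or two when the overlap is a
    # small fraction of the tile: hill-climb on overlap NCC to the local max
    off, score = np.round(best[0]), best[1]
    improved = True
    while improved:
        improved = False
        for ax in range(3):
            for d in (-1, 1):
                cand = off.copy()
                cand[ax] += d
                s = _ncc_at_offset(a, b, cand)
                if s > score:
                    off, score = cand, s
                    improved = True
    return off, score


def estimate_tile_offsets(
    tiles: list[VoxelGrid],
    layout: TileLayout,
    reference_channel: str = "sum",
    ncc_threshold: float = 0.3,
    subpixel: bool = False,
):
    """Estimate pairwise offsets and global positions for a tile grid.

    Returns ``(pairs, positions)``: ``pairs`` is a list of
    ``(i, j, offset_zyx, score, used_fallback)`` for each grid-adjacent tile
    pair, and ``positions`` an ``(n_tiles, 3)`` integer array of global
    ``(z, y, x)`` origins anchored at the first tile.
    """
    if len(tiles) == 0:
        raise ValueError("no tiles given")
    if len(tiles) != layout.n_tiles:
        raise ValueError(f"{len(tiles)} tiles for a {layout.rows}x{layout.cols} grid")
    shapes = {t.data.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent tile shapes: {sorted(shapes)}")
    if len(tiles) == 1:
        return [], np.zeros((1, 3), dtype=int)

    refs = [_reference_image(t, reference_channel) for t in tiles]
    shape_yx = (
        round(layout.rows * refs[0].shape[1] * (1 - layout.overlap))
        + round(refs[0].shape[1] * layout.overlap),
        round(layout.cols * refs[0].shape[2] * (1 - layout.overlap))
        + round(refs[0].shape[2] * layout.overlap),
    )
    th, tw = refs[0].shape[1], refs[0].shape[2]
    step_y = round(th * (1 - layout.overlap))
    step_x = round(tw * (1 - layout.overlap))

    pairs = []
    for r in range(layout.rows):
        for c in range(layout.cols):
            i = layout.index(r, c)
            for (dr, dc, nominal) in (
                (0, 1, (0, 0, step_x)),
                (1, 0, (0, step_y, 0)),
            ):
                r2, c2 = r + dr, c + dc
                if r2 >= layout.rows or c2 >= layout.cols:
                    continue
                j = layout.index(r2, c2)
                offset, score = _pairwise_offset(
                    refs[i], refs[j], nominal, subpixel=subpixel
                )
                fallback = score < ncc_threshold
                if fallback:
                    offset = np.asarray(nominal, dtype=float)
                pairs.append((i, j, offset, score, fallback))

    # least squares on the offset graph, anchored at tile 0
    n = len(tiles)
    a_mat = np.zeros((len(pairs) + 1, n))
    rhs = np.zeros((len(pairs) + 1, 3))
    for row, (i, j, off, _, _) in enumerate(pairs):
        a_mat[row, i] = -1.0
        a_mat[row, j] = 1.0
        rhs[row] = off
    a_mat[-1, 0] = 1.0  # anchor
    sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    positions = sol - sol[0]
    if not subpixel:
        positions = np.round(positions)
    positions = positions - positions.min(axis=0)
    return pairs, (
        positions.astype(int) if not subpixel else positions
    )


def fuse_tiles(
    tiles: list[VoxelGrid],
    positions: np.ndarray,
    blend: bool = True,
    section_index: int = 0,
) -> MacrosectionStack:
    """Fuse positioned tiles onto one canvas.

    Overlap regions are blended with a separable linear distance-to-edge ramp
    (so equal overlapping values pass through unchanged); with ``blend=False``
    later tiles simply overwrite earlier ones.
    """
    if len(tiles) == 0:
        raise ValueError("no tiles given")
    positions = np.atleast_2d(np.asarray(positions))
    if len(positions) != len(tiles):
        raise ValueError("one position per tile required")
    if positions.min() < 0:
        positions = positions - positions.min(axis=0)
    first = tiles[0]
    dtype = first.data.dtype
    tz, ty, tx = first.data.shape[1:]
    canvas_shape = tuple(
        int(np.ceil(positions[:, ax].max())) + first.data.shape[1 + ax]
        for ax in range(3)
    )
    nch = first.n_channels
    acc = np.zeros((nch,) + canvas_shape, dtype=np.float64)
    wsum = np.zeros(canvas_shape, dtype=np.float64)

    ramps = [
        np.minimum(np.arange(m) + 1, m - np.arange(m)).astype(np.float64)
        for m in (tz, ty, tx)
    ]
    w_tile = ramps[0][:, None, None] * ramps[1][None, :, None] * ramps[2][None, None, :]

    for tile, pos in zip(tiles, positions):
        if tile.data.shape != first.data.shape:
            raise ValueError("inconsistent tile shapes")
        z0, y0, x0 = (int(round(p)) for p in pos)
        sl = (slice(z0, z0 + tz), slice(y0, y0 + ty), slice(x0, x0 + tx))
        if blend:
            acc[(slice(None),) + sl] += tile.data.astype(np.float64) * w_tile
            wsum[sl] += w_tile
        else:
            acc[(slice(None),) + sl] = tile.data
            wsum[sl] = 1.0

    out = np.divide(acc, wsum, out=np.zeros_like(acc), where=wsum > 0)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        out = np.clip(np.round(out), info.min, info.max).astype(dtype)
    else:
        out = out.astype(dtype)
    grid = VoxelGrid(out, first.spacing, list(first.channel_names))
    return MacrosectionStack(grid=grid, section_index=section_index)


def stitch_tiles(
    tiles: list[VoxelGrid],
    layout: TileLayout,
    reference_channel: str = "sum",
    ncc_threshold: float = 0.3,
    section_index: int = 0,
):
    """Convenience: estimate offsets then fuse; returns (stack, pairs, positions)."""
    pairs, positions = estimate_tile_offsets(
        tiles, layout, reference_channel, ncc_threshold=ncc_threshold
    )
    stack = fuse_tiles(tiles, positions, section_index=section_index)
    return stack, pairs, positions


__all__ = [
    "TileLayout",
    "tile_size_for_layout",
    "nominal_tile_origins",
    "estimate_tile_offsets",
    "fuse_tiles",
    "stitch_tiles",
]
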