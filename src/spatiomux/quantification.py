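"""Tile-streamed per-cell intensity quantification.

Computes per-cell statistics (mean, sum, max) of a registered image —
typically an immunofluorescence channel aligned into the omics frame —
without ever materializing the full image: the image is traversed in
disjoint row-major tiles, each cell keeps a running (sum, count, max)
accumulator, and cells straddling tile borders are merged exactly because
all three statistics are associative. Results are therefore independent
of the tile size (bit-for-bit for integer images; the mean is a single
division at the end).

A pixel belongs to a cell iff its center lies inside the cell's boundary
polygon (boundary inclusive, matching the package-wide point-in-polygon
rule), or — when a label mask image is supplied — iff it carries the
cell's label; the mask takes precedence over polygons. The median is not
offered: it cannot be merged across tiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .core import CellLayer, PixelImage

logger = logging.getLogger(__name__)

STATS = ("mean", "sum", "max")


@dataclass
class TileSpec:
    """Tiling contract: square tiles of ``tile_size`` px, row-major, no overlap."""

    tile_size: int = 1024

    def __post_init__(self):
        if self.tile_size < 1:
            raise ValueError("tile_size must be >= 1")


def iter_tiles(image_shape: tuple[int, int], spec: TileSpec) -> Iterator[tuple[int, int, int, int]]:
    """Yield (r0, r1, c0, c1) windows tiling the image exactly once.

    Windows are disjoint, cover every pixel, and are truncated at the
    bottom/right edges.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    t = spec.tile_size
    for r0 in range(0, h, t):
        for c0 in range(0, w, t):
            yield r0, min(r0 + t, h), c0, min(c0 + t, w)


def _channel_plane(region: np.ndarray, channel: int) -> np.ndarray:
    if region.ndim == 2:
        if channel != 0:
            raise KeyError(f"single-channel image has no channel {channel}")
        return region
    if channel >= region.shape[2]:
        raise KeyError(f"image has {region.shape[2]} channels, no channel {channel}")
    return region[..., channel]


def quantify_intensity(
    image: PixelImage,
    cell_layer: CellLayer,
    channel: int | str = 0,
    stats: Sequence[str] = ("mean", "sum", "max"),
    tile_spec: TileSpec | int | None = None,
    boundary: str = "cellular",
    label_mask: PixelImage | None = None,
) -> CellLayer:
    """Append per-cell intensity statistics to a cell layer.

    Parameters
    ----------
    image : registered image in the sample's µm frame (lazy handles are
        read window-by-window, never fully).
    channel : channel index or name; resolved against ``image.channel_names``.
    stats : subset of {"mean", "sum", "max"}.
    tile_spec : tile size in px (int or :class:`TileSpec`); default 1024.
    boundary : which boundary polygon defines a cell's footprint
        ("cellular", the default, or "nuclear").
    label_mask : optional integer label image on the same pixel grid;
        pixel label == position of the cell in the cell table + 1 (0 is
        background). When given it takes precedence over polygons.

    Returns the same layer with new columns ``<channel>_<stat>``; cells
    covering no pixel get NaN and a warning is logged.
    """
    if isinstance(tile_spec, int):
        tile_spec = TileSpec(tile_spec)
    spec = tile_spec or TileSpec()
    bad = set(stats) - set(STATS)
    if bad:
        raise ValueError(f"unsupported statistics {sorted(bad)}; streaming supports {STATS}")

    if isinstance(channel, str):
        if channel not in image.channel_names:
            raise KeyError(f"unknown channel {channel!r}; image has {image.channel_names}")
        ch_idx = image.channel_names.index(channel)
        ch_name = channel
    else:
        ch_idx = int(channel)
        if ch_idx >= image.n_channels:
            raise KeyError(f"image has {image.n_channels} channels, no channel {ch_idx}")
        ch_name = image.channel_names[ch_idx]

    n = cell_layer.n_cells
    sums = np.zeros(n, dtype=np.float64)
    counts = np.zeros(n, dtype=np.int64)
    maxs = np.full(n, -np.inf)
    s = image.pixel_size
    ox, oy = image.origin
    h, w = image.height, image.width

    if label_mask is None:
        if boundary not in cell_layer.boundaries:
            raise ValueError(
                f"cell layer has no {boundary!r} boundaries and no label mask was given"
            )
        polys = cell_layer.boundaries[boundary]
        ids = cell_layer.cell_table["cell_id"].astype(str).tolist()
        geoms, owners, bboxes = [], [], []
        for i, cid in enumerate(ids):
            ring = polys.get(cid)
            if ring is None:
                continue
            g = Polygon(ring)
            shapely.prepare(g)
            geoms.append(g)
            owners.append(i)
            bboxes.append(g.bounds)
        bboxes = np.asarray(bboxes).reshape(-1, 4)

        for r0, r1, c0, c1 in iter_tiles((h, w), spec):
            # µm extent of this tile (pixel centers it contains)
            tx0, ty0 = c0 * s + ox, r0 * s + oy
            tx1, ty1 = c1 * s + ox, r1 * s + oy
            hit = np.nonzero(
                (bboxes[:, 0] < tx1) & (bboxes[:, 2] >= tx0)
                & (bboxes[:, 1] < ty1) & (bboxes[:, 3] >= ty0)
            )[0]
            if len(hit) == 0:
                continue
            region = _channel_plane(np.asarray(image.read_region(r0, r1, c0, c1)), ch_idx)
            for k in hit:
                g, i = geoms[k], owners[k]
                bx0, by0, bx1, by1 = bboxes[k]
                # pixel-index range of the cell bbox clipped to this tile
                ca = max(c0, int(np.floor((bx0 - ox) / s)))
                cb = min(c1, int(np.ceil((bx1 - ox) / s)) + 1)
                ra = max(r0, int(np.floor((by0 - oy) / s)))
                rb = min(r1, int(np.ceil((by1 - oy) / s)) + 1)
                if ca >= cb or ra >= rb:
                    continue
                cols = np.arange(ca, cb)
                rows = np.arange(ra, rb)
                cx = (cols + 0.5) * s + ox
                cy = (rows + 0.5) * s + oy
                gx, gy = np.meshgrid(cx, cy)
                inside = shapely.covers(g, shapely.points(gx.ravel(), gy.ravel()))
                if not inside.any():
                    continue
                vals = region[ra - r0 : rb - r0, ca - c0 : cb - c0].ravel()[inside]
                sums[i] += np.float64(vals.sum(dtype=np.float64))
                counts[i] += vals.size
                maxs[i] = max(maxs[i], float(vals.max()))
    else:
        if label_mask.shape[:2] != (h, w):
            raise ValueError("label mask must share the image's pixel grid")
        for r0, r1, c0, c1 in iter_tiles((h, w), spec):
            region = _channel_plane(np.asarray(image.read_region(r0, r1, c0, c1)), ch_idx)
            labels = np.asarray(label_mask.read_region(r0, r1, c0, c1)).astype(np.int64)
            sel = labels > 0
            if not sel.any():
                continue
            idx = labels[sel] - 1
            vals = region[sel].astype(np.float64)
            np.add.at(sums, idx, vals)
            np.add.at(counts, idx, 1)
            np.maximum.at(maxs, idx, vals)

    covered = counts > 0
    if not covered.all():
        logger.warning("%d cells cover no image pixel; statistics set to NaN", (~covered).sum())
    table = cell_layer.cell_table
    with np.errstate(invalid="ignore", divide="ignore"):
        computed = {
            "mean": np.where(covered, sums / np.maximum(counts, 1), np.nan),
            "sum": np.where(covered, sums, np.nan),
            "max": np.where(covered, maxs, np.nan),
        }
    for stat in stats:
        table[f"{ch_name}_{stat}"] = computed[stat]
    return cell_layer
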