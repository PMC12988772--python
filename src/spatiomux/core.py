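"""Sample-level data model.

A :class:`Sample` is the container for one tissue section. Its contents are
organized into six data categories:

``images``
    Named pixel images (nuclear stain, post-run histology, ...) with a
    physical pixel size.
``transcripts``
    A table of individual molecule detections (x, y in µm, gene label,
    optional quality and cell assignment).
``cells``
    One :class:`CellLayer` per segmentation: a count matrix, a per-cell
    table, a per-feature table, and optional nuclear/cellular boundary
    polygons.
``units``
    Like cells, but for arbitrary spatial units (capture spots, tissue
    compartments); every unit carries a shape polygon.
``annotations``
    Named :class:`PolygonSet` objects labelling histology ("tumor", ...).
``regions``
    Named :class:`PolygonSet` objects delineating structural units such as
    TMA cores or sections, used to split a dataset into samples.

Coordinate convention: one shared µm frame anchored at the top-left corner
of the primary image; x runs rightward along columns, y downward along
rows. The center of pixel (row r, column c) sits at ((c+0.5)·s, (r+0.5)·s)
for pixel size s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, box

from ._exceptions import InvalidPolygonError, NoExtentError
from .geometry import as_ring, points_in_polygon

logger = logging.getLogger(__name__)

CATEGORIES = ("images", "transcripts", "cells", "units", "annotations", "regions")

TRANSCRIPT_COLUMNS = ("x", "y", "gene")


class PixelImage:
    """A 2-D (or 2-D + channels) pixel image with a physical pixel size.

    The pixel payload may be provided eagerly as an array, or lazily as a
    pair of callables so that opening a project never reads pixels until
    they are accessed:

    ``loader()``
        returns the full array;
    ``region_loader(r0, r1, c0, c1)``
        returns the window ``[r0:r1, c0:c1]`` without materializing the
        rest (used by tile-streamed quantification).

    ``shape`` must be supplied for lazy images and is always available
    without touching the payload.

    ``origin`` is the µm position of pixel (0, 0) in the sample frame;
    it is (0, 0) for acquired images and becomes non-zero when a sample
    is cropped without shifting the coordinate origin, keeping image and
    µm coordinates consistent.
    """

    def __init__(
        self,
        pixels: np.ndarray | None = None,
        pixel_size: float = 1.0,
        channel_names: list[str] | None = None,
        name: str = "",
        *,
        origin: tuple[float, float] = (0.0, 0.0),
        loader: Callable[[], np.ndarray] | None = None,
        region_loader: Callable[[int, int, int, int], np.ndarray] | None = None,
        shape: tuple[int, ...] | None = None,
        dtype=None,
    ):
        if pixels is None and loader is None:
            raise ValueError("either pixels or a loader is required")
        if pixels is not None:
            pixels = np.asarray(pixels)
            shape = pixels.shape
            dtype = pixels.dtype
        if shape is None:
            raise ValueError("lazy images must declare their shape")
        if len(shape) not in (2, 3) or shape[0] < 1 or shape[1] < 1:
            raise ValueError(f"image shape must be (H, W) or (H, W, C) with H, W >= 1, got {shape}")
        if not pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {pixel_size}")
        n_channels = shape[2] if len(shape) == 3 else 1
        if channel_names is None:
            channel_names = [f"ch{i}" for i in range(n_channels)]
        if len(channel_names) != n_channels:
            raise ValueError(
                f"{len(channel_names)} channel names for {n_channels} channels"
            )
        self._pixels = pixels
        self._loader = loader
        self._region_loader = region_loader
        self._shape = tuple(shape)
        self._dtype = np.dtype(dtype) if dtype is not None else None
        self.pixel_size = float(pixel_size)
        self.channel_names = list(channel_names)
        self.name = name
        self.origin = (float(origin[0]), float(origin[1]))

    # -- payload-free metadata -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self._shape

    @property
    def height(self) -> int:
        return self._shape[0]

    @property
    def width(self) -> int:
        return self._shape[1]

    @property
    def n_channels(self) -> int:
        return self._shape[2] if len(self._shape) == 3 else 1

    @property
    def dtype(self):
        return self._dtype

    @property
    def is_loaded(self) -> bool:
        """True once the full pixel payload has been materialized."""
        return self._pixels is not None

    # -- payload access ---------------------------------------------------
    @property
    def pixels(self) -> np.ndarray:
        """The full pixel array; triggers the loader on first access."""
        if self._pixels is None:
            self._pixels = np.asarray(self._loader())
            if self._pixels.shape != self._shape:
                raise ValueError(
                    f"loader returned shape {self._pixels.shape}, manifest says {self._shape}"
                )
        return self._pixels

    def read_region(self, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
        """Window ``[r0:r1, c0:c1]``, read without full materialization when possible."""
        if self._pixels is not None:
            return self._pixels[r0:r1, c0:c1]
        if self._region_loader is not None:
            return np.asarray(self._region_loader(r0, r1, c0, c1))
        return self.pixels[r0:r1, c0:c1]

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the image in µm."""
        s = self.pixel_size
        ox, oy = self.origin
        return (ox, oy, ox + self.width * s, oy + self.height * s)

    def __repr__(self):
        state = "loaded" if self.is_loaded else "lazy"
        return f"PixelImage({self.name!r}, shape={self._shape}, pixel_size={self.pixel_size}, {state})"


def validate_transcripts(df: pd.DataFrame) -> pd.DataFrame:
    """Check the transcript-table contract: finite x/y, non-empty gene labels."""
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transcript table missing columns {missing}")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    if len(df) and not np.all(np.isfinite(xy)):
        raise ValueError("transcript coordinates must be finite")
    if len(df) and (df["gene"].astype(str) == "").any():
        raise ValueError("transcript gene labels must be non-empty")
    return df


BOUNDARY_KINDS = ("nuclear", "cellular")


@dataclass
class CellLayer:
    """One segmentation's worth of per-cell data.

    Attributes
    ----------
    matrix : ndarray or scipy sparse, (n_cells, n_features) non-negative counts.
    cell_table : one row per cell; requires ``cell_id`` (unique),
        ``centroid_x``/``centroid_y`` in µm; further columns (cell_type,
        quantified intensities, ...) are free.
    feature_table : one row per feature; requires ``feature``.
    boundaries : {"nuclear": {cell_id: ring}, "cellular": {...}} — either
        kind may be absent; rings are implicitly closed (n, 2) µm arrays.
    """

    matrix: object
    cell_table: pd.DataFrame
    feature_table: pd.DataFrame
    boundaries: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.matrix.shape[0] != len(self.cell_table):
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but cell_table has {len(self.cell_table)}"
            )
        if self.matrix.shape[1] != len(self.feature_table):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but feature_table has {len(self.feature_table)}"
            )
        for col in ("cell_id", "centroid_x", "centroid_y"):
            if col not in self.cell_table.columns:
                raise ValueError(f"cell_table missing column {col!r}")
        if "feature" not in self.feature_table.columns:
            raise ValueError("feature_table missing column 'feature'")
        ids = self.cell_table["cell_id"]
        if ids.duplicated().any():
            raise ValueError("cell_ids must be unique")
        known = set(ids.astype(str))
        for kind, polys in self.boundaries.items():
            if kind not in BOUNDARY_KINDS:
                raise ValueError(f"unknown boundary kind {kind!r}")
            stray = set(map(str, polys)) - known
            if stray:
                raise ValueError(f"{kind} boundaries reference unknown cell_ids {sorted(stray)[:3]}")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def features(self) -> pd.Index:
        return pd.Index(self.feature_table["feature"].astype(str))

    def dense_matrix(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if hasattr(m, "toarray") else np.asarray(m)

    def centroids(self) -> np.ndarray:
        return self.cell_table[["centroid_x", "centroid_y"]].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "CellLayer":
        """New layer keeping cells where *mask* is true; matrix rows and boundaries follow."""
        mask = np.asarray(mask, dtype=bool)
        table = self.cell_table.loc[mask].reset_index(drop=True)
        kept = set(table["cell_id"].astype(str))
        bounds = {
            kind: {cid: ring for cid, ring in polys.items() if str(cid) in kept}
            for kind, polys in self.boundaries.items()
        }
        return CellLayer(self.matrix[mask], table, self.feature_table.copy(), bounds)

    def translate(self, dx: float, dy: float) -> None:
        self.cell_table["centroid_x"] += dx
        self.cell_table["centroid_y"] += dy
        for polys in self.boundaries.values():
            for cid in polys:
                polys[cid] = polys[cid] + np.array([dx, dy])


@dataclass
class UnitLayer:
    """Spatial-unit layer: like a cell layer but every unit has a shape polygon."""

    matrix: object
    unit_table: pd.DataFrame
    feature_table: pd.DataFrame
    shapes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.matrix.shape[0] != len(self.unit_table):
            raise ValueError("matrix rows != unit_table rows")
        if self.matrix.shape[1] != len(self.feature_table):
            raise ValueError("matrix columns != feature_table rows")
        for col in ("unit_id", "centroid_x", "centroid_y"):
            if col not in self.unit_table.columns:
                raise ValueError(f"unit_table missing column {col!r}")
        if self.unit_table["unit_id"].duplicated().any():
            raise ValueError("unit_ids must be unique")
        missing = set(self.unit_table["unit_id"].astype(str)) - set(map(str, self.shapes))
        if missing:
            raise ValueError(f"units without shape polygon: {sorted(missing)[:3]}")

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    def centroids(self) -> np.ndarray:
        return self.unit_table[["centroid_x", "centroid_y"]].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "UnitLayer":
        mask = np.asarray(mask, dtype=bool)
        table = self.unit_table.loc[mask].reset_index(drop=True)
        kept = set(table["unit_id"].astype(str))
        shapes = {uid: ring for uid, ring in self.shapes.items() if str(uid) in kept}
        return UnitLayer(self.matrix[mask], table, self.feature_table.copy(), shapes)

    def translate(self, dx: float, dy: float) -> None:
        self.unit_table["centroid_x"] += dx
        self.unit_table["centroid_y"] += dy
        for uid in self.shapes:
            self.shapes[uid] = self.shapes[uid] + np.array([dx, dy])


@dataclass
class PolygonEntry:
    name: str
    class_label: str
    vertices: np.ndarray  # implicitly closed (n, 2) ring, µm

    def __post_init__(self):
        self.vertices = as_ring(self.vertices)


@dataclass
class PolygonSet:
    """Named, classed polygons.

    ``scope`` distinguishes the two uses: *annotations* label histology
    (class = e.g. "tumor"); *regions* delineate structural units (TMA
    cores, sections) and drive region-based experiment assembly.
    """

    scope: str
    entries: list[PolygonEntry] = field(default_factory=list)

    def __post_init__(self):
        if self.scope not in ("annotation", "region"):
            raise ValueError(f"scope must be 'annotation' or 'region', got {self.scope!r}")
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("polygon names must be unique within a set")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def add(self, name: str, class_label: str, vertices) -> None:
        if any(e.name == name for e in self.entries):
            raise ValueError(f"duplicate polygon name {name!r}")
        self.entries.append(PolygonEntry(name, class_label, vertices))

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def translate(self, dx: float, dy: float) -> None:
        for e in self.entries:
            e.vertices = e.vertices + np.array([dx, dy])


@dataclass
class Sample:
    """Per-tissue-section container holding the six data categories."""

    uid: str | None = None
    metadata: dict = field(default_factory=dict)
    images: dict[str, PixelImage] = field(default_factory=dict)
    transcripts: object = None  # DataFrame, lazy table handle, or None
    cells: dict[str, CellLayer] = field(default_factory=dict)
    units: dict[str, UnitLayer] = field(default_factory=dict)
    annotations: dict[str, PolygonSet] = field(default_factory=dict)
    regions: dict[str, PolygonSet] = field(default_factory=dict)

    def transcripts_frame(self) -> pd.DataFrame | None:
        """Transcripts as a DataFrame, materializing a lazy handle if needed."""
        t = self.transcripts
        if t is None:
            return None
        if isinstance(t, pd.DataFrame):
            return t
        return t.load()  # lazy table handle from storage

    @property
    def primary_image(self) -> PixelImage | None:
        if not self.images:
            return None
        if "nuclei" in self.images:
            return self.images["nuclei"]
        return next(iter(self.images.values()))

    def n_cells(self) -> int:
        return sum(layer.n_cells for layer in self.cells.values())

    def n_transcripts(self) -> int:
        t = self.transcripts
        if t is None:
            return 0
        return len(t) if isinstance(t, pd.DataFrame) else t.n_rows


def get_extent(sample: Sample) -> tuple[float, float, float, float]:
    """Tight bounding box (xmin, ymin, xmax, ymax) in µm.

    Prefers the primary image's footprint; falls back to the bounding box
    of all cell centroids. Raises :class:`NoExtentError` if the sample has
    neither an image nor cells.
    """
    img = sample.primary_image
    if img is not None:
        return img.extent()
    cents = [layer.centroids() for layer in sample.cells.values() if layer.n_cells]
    if cents:
        pts = np.vstack(cents)
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )
    raise NoExtentError("sample has no image and no cells; extent undefined")


def full_extent_polygon(sample: Sample) -> np.ndarray:
    x0, y0, x1, y1 = get_extent(sample)
    return np.array([(x0, y0), (x1, y0), (x1, y1), (x0, y1)], dtype=float)


def _clip_polygon_set(pset: PolygonSet, clip_box: Polygon) -> PolygonSet:
    out = PolygonSet(scope=pset.scope)
    for e in pset.entries:
        inter = Polygon(e.vertices).intersection(clip_box)
        if inter.is_empty or inter.area == 0:
            continue
        parts = list(inter.geoms) if isinstance(inter, MultiPolygon) else [inter]
        parts = [p for p in parts if isinstance(p, Polygon) and p.area > 0]
        for i, part in enumerate(parts):
            name = e.name if len(parts) == 1 else f"{e.name}_part{i}"
            out.add(name, e.class_label, np.asarray(part.exterior.coords)[:-1])
    return out


def crop_sample(sample: Sample, polygon, shift_origin: bool = False) -> Sample:
    """Spatially subset a sample by a polygon.

    Cells and units are kept iff their centroid lies inside the polygon
    (boundary inclusive); whole matrix rows and boundary polygons follow.
    Transcripts are kept iff the molecule position is inside. Images are
    cropped to the polygon's pixel-aligned bounding box; annotation and
    region sets are clipped to that bounding box. With ``shift_origin``,
    all coordinates are translated so the bounding-box minimum maps to
    (0, 0); the applied offset is recorded in ``metadata['crop_offset_um']``
    so the crop is invertible.

    A polygon entirely outside the extent yields an empty sample (with a
    warning), not an error.
    """
    ring = as_ring(polygon)
    bx0, by0 = ring.min(axis=0)
    bx1, by1 = ring.max(axis=0)

    ex = None
    try:
        ex = get_extent(sample)
    except NoExtentError:
        pass
    if ex is not None and (bx1 < ex[0] or bx0 > ex[2] or by1 < ex[1] or by0 > ex[3]):
        logger.warning("crop polygon lies outside the sample extent; result is empty")

    # pixel-aligned bbox on the primary image grid (falls back to raw bbox)
    primary = sample.primary_image
    if primary is not None:
        s = primary.pixel_size
        pox, poy = primary.origin
        ax0 = max(pox + math.floor((bx0 - pox) / s) * s, pox)
        ay0 = max(poy + math.floor((by0 - poy) / s) * s, poy)
        ax1 = pox + math.ceil((bx1 - pox) / s) * s
        ay1 = poy + math.ceil((by1 - poy) / s) * s
    else:
        ax0, ay0, ax1, ay1 = bx0, by0, bx1, by1

    out = Sample(uid=sample.uid, metadata=dict(sample.metadata))

    for name, img in sample.images.items():
        s = img.pixel_size
        ox, oy = img.origin
        c0 = max(0, math.floor((bx0 - ox) / s))
        r0 = max(0, math.floor((by0 - oy) / s))
        c1 = min(img.width, math.ceil((bx1 - ox) / s))
        r1 = min(img.height, math.ceil((by1 - oy) / s))
        if r1 <= r0 or c1 <= c0:
            logger.warning("image %r does not intersect the crop bbox; dropped", name)
            continue
        out.images[name] = PixelImage(
            img.read_region(r0, r1, c0, c1),
            pixel_size=s,
            channel_names=list(img.channel_names),
            name=img.name,
            origin=(ox + c0 * s, oy + r0 * s),
        )

    t = sample.transcripts_frame()
    if t is not None:
        mask = points_in_polygon(t[["x", "y"]].to_numpy(dtype=float), ring)
        out.transcripts = t.loc[mask].reset_index(drop=True)

    for lname, layer in sample.cells.items():
        out.cells[lname] = layer.subset(points_in_polygon(layer.centroids(), ring))
    for lname, layer in sample.units.items():
        out.units[lname] = layer.subset(points_in_polygon(layer.centroids(), ring))

    clip = box(ax0, ay0, max(ax1, ax0), max(ay1, ay0))
    for name, pset in sample.annotations.items():
        out.annotations[name] = _clip_polygon_set(pset, clip)
    for name, pset in sample.regions.items():
        out.regions[name] = _clip_polygon_set(pset, clip)

    if shift_origin:
        dx, dy = -ax0, -ay0
        for img in out.images.values():
            img.origin = (img.origin[0] + dx, img.origin[1] + dy)
        if out.transcripts is not None and len(out.transcripts):
            out.transcripts["x"] += dx
            out.transcripts["y"] += dy
        for layer in out.cells.values():
            layer.translate(dx, dy)
        for layer in out.units.values():
            layer.translate(dx, dy)
        for pset in out.annotations.values():
            pset.translate(dx, dy)
        for pset in out.regions.values():
            pset.translate(dx, dy)
        out.metadata["crop_offset_um"] = (float(ax0), float(ay0))
    return out
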