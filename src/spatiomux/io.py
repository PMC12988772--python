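"""On-disk project format, lazy loaders, GeoJSON interchange, flat export.

Project layout
--------------
A sample project is a directory::

    project/
      manifest.json                     # inventory, checksums, timestamps
      static/
        images/<name>.tif               # tiled TIFF
        images/<name>.meta.json         # pixel_size, channel_names
        transcripts.parquet             # (CSV fallback: transcripts.csv)
      variable/
        cells/<layer>/matrix.mtx
        cells/<layer>/cells.csv
        cells/<layer>/features.csv
        cells/<layer>/boundaries.geojson
        units/<layer>/{matrix.mtx,units.csv,features.csv,shapes.geojson}
        annotations/<set>.geojson
        regions/<set>.geojson
        metadata.json

Static data (raw images, transcript positions) never changes during
analysis: it is written once by :func:`saveas` together with SHA-256
digests recorded in the manifest. :func:`save` to an existing project
rewrites only the ``variable`` subtree, which keeps incremental saves
fast and leaves every static file byte-identical.

Images and transcripts load lazily: :func:`load_project` reads only
headers (shape, dtype, row counts); pixel and point payloads materialize
on first access, with windowed pixel reads served from the TIFF tiles.

An experiment project is a directory with ``experiment.json``,
``metadata.csv`` and one sample project per sample under ``samples/``.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile
import zarr

from ._exceptions import ProjectError
from .core import (
    CellLayer,
    PixelImage,
    PolygonEntry,
    PolygonSet,
    Sample,
    UnitLayer,
    validate_transcripts,
)
from .geometry import as_ring

logger = logging.getLogger(__name__)

MANIFEST = "manifest.json"
FORMAT_VERSION = "1.0"


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


class LazyTable:
    """Lazy handle on an on-disk table (parquet or CSV).

    Opening reads only file metadata (row count, column names); the row
    payload is read on first :meth:`load` and cached. ``payload_reads``
    counts actual payload materializations, which lets tests assert the
    laziness contract.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._df: pd.DataFrame | None = None
        self.payload_reads = 0
        if self.path.suffix == ".parquet":
            import pyarrow.parquet as pq

            meta = pq.ParquetFile(self.path)
            self.n_rows = meta.metadata.num_rows
            self.columns = list(meta.schema_arrow.names)
        else:
            head = pd.read_csv(self.path, nrows=0)
            self.columns = list(head.columns)
            with open(self.path) as fh:
                self.n_rows = sum(1 for _ in fh) - 1

    @property
    def loaded(self) -> bool:
        return self._df is not None

    def load(self) -> pd.DataFrame:
        if self._df is None:
            self.payload_reads += 1
            if self.path.suffix == ".parquet":
                self._df = pd.read_parquet(self.path)
            else:
                self._df = pd.read_csv(self.path)
        return self._df

    def __len__(self) -> int:
        return self.n_rows


def _lazy_tiff_image(path: Path, meta: dict) -> PixelImage:
    """Lazy PixelImage over a TIFF; windowed reads go through the tile grid."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        shape, dtype = page.shape, page.dtype

    state: dict = {}

    def _zarr():
        if "z" not in state:
            state["z"] = zarr.open(tifffile.imread(path, aszarr=True), mode="r")
        return state["z"]

    return PixelImage(
        pixel_size=meta["pixel_size"],
        channel_names=meta.get("channel_names"),
        name=meta.get("name", path.stem),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        loader=lambda: tifffile.imread(path),
        region_loader=lambda r0, r1, c0, c1: np.asarray(_zarr()[r0:r1, c0:c1]),
        shape=shape,
        dtype=dtype,
    )


# ---------------------------------------------------------------------------
# GeoJSON interchange (QuPath classification dialect)
# ---------------------------------------------------------------------------

def export_annotations_geojson(polygon_set: PolygonSet, path: str | Path) -> None:
    """Write a polygon set as a GeoJSON FeatureCollection.

    Rings are explicitly closed; the class label goes into the QuPath-style
    ``classification.name`` property; a top-level ``coordinate_unit``
    property declares micrometre coordinates.
    """
    features = []
    for e in polygon_set:
        ring = e.vertices.tolist()
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "name": e.name,
                    "classification": {"name": e.class_label},
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "coordinate_unit": "micron",
        "scope": polygon_set.scope,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _feature_class(props: dict) -> str:
    cls = props.get("classification")
    if isinstance(cls, dict) and cls.get("name"):
        return str(cls["name"])
    if isinstance(cls, str) and cls:
        return cls
    return "unclassified"


def import_annotations_geojson(
    path: str | Path, scope: str, pixel_size: float | None = None
) -> PolygonSet:
    """Read a GeoJSON FeatureCollection of polygons into a :class:`PolygonSet`.

    The top-level ``coordinate_unit`` property selects "micron" (default
    when absent) or "pixel"; pixel coordinates — the QuPath convention —
    are converted to µm with the declared or caller-supplied pixel size.
    Non-polygon geometries are skipped with a warning; each ring of a
    MultiPolygon becomes its own entry sharing the feature's name stem.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    unit = doc.get("coordinate_unit", "micron")
    scale = 1.0
    if unit == "pixel":
        s = doc.get("pixel_size", pixel_size)
        if s is None:
            raise ValueError(f"{path}: pixel coordinates but no pixel size declared or supplied")
        scale = float(s)

    pset = PolygonSet(scope=scope)
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        name = str(props.get("name", f"feature_{i}"))
        cls = _feature_class(props)
        gtype = geom.get("type")
        if gtype == "Polygon":
            rings = [geom["coordinates"][0]]
        elif gtype == "MultiPolygon":
            rings = [poly[0] for poly in geom["coordinates"]]
        else:
            logger.warning("%s: skipping non-polygon geometry %r (feature %d)", path, gtype, i)
            continue
        for j, ring in enumerate(rings):
            entry_name = name if len(rings) == 1 else f"{name}_{j}"
            if any(e.name == entry_name for e in pset.entries):
                entry_name = f"{entry_name}_{i}"
            pset.add(entry_name, cls, np.asarray(ring, dtype=float) * scale)
    return pset


def _boundaries_to_geojson(layer_boundaries: dict, path: Path) -> None:
    features = []
    for kind, polys in layer_boundaries.items():
        for cid, ring_arr in polys.items():
            ring = np.asarray(ring_arr).tolist()
            ring.append(ring[0])
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {"cell_id": str(cid), "boundary_type": kind},
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "coordinate_unit": "micron", "features": features}, fh)


def _boundaries_from_geojson(path: Path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    out: dict[str, dict[str, np.ndarray]] = {}
    for feat in doc.get("features", []):
        props = feat["properties"]
        kind = props["boundary_type"]
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        out.setdefault(kind, {})[str(props["cell_id"])] = as_ring(ring)
    return out


# ---------------------------------------------------------------------------
# per-category writers / readers
# ---------------------------------------------------------------------------

def _write_image(img: PixelImage, dirpath: Path, name: str) -> list[Path]:
    dirpath.mkdir(parents=True, exist_ok=True)
    tif = dirpath / f"{name}.tif"
    pixels = img.pixels
    tile = (256, 256) if min(pixels.shape[:2]) >= 16 else None
    tifffile.imwrite(tif, pixels, tile=tile)
    meta = dirpath / f"{name}.meta.json"
    with open(meta, "w") as fh:
        json.dump(
            {"pixel_size": img.pixel_size, "channel_names": img.channel_names,
             "name": img.name, "origin": list(img.origin)},
            fh,
        )
    return [tif, meta]


def _write_matrix_layer(matrix, tables: dict[str, pd.DataFrame], dirpath: Path) -> None:
    dirpath.mkdir(parents=True, exist_ok=True)
    m = sp.coo_matrix(matrix)
    scipy.io.mmwrite(dirpath / "matrix.mtx", m)
    for fname, df in tables.items():
        df.to_csv(dirpath / fname, index=False)


def _read_matrix(path: Path):
    return sp.csr_matrix(scipy.io.mmread(path))


def _write_cell_layer(layer: CellLayer, dirpath: Path) -> None:
    _write_matrix_layer(
        layer.matrix,
        {"cells.csv": layer.cell_table, "features.csv": layer.feature_table},
        dirpath,
    )
    if layer.boundaries:
        _boundaries_to_geojson(layer.boundaries, dirpath / "boundaries.geojson")


def _read_cell_layer(dirpath: Path) -> CellLayer:
    matrix = _read_matrix(dirpath / "matrix.mtx")
    cells = pd.read_csv(dirpath / "cells.csv", dtype={"cell_id": str})
    feats = pd.read_csv(dirpath / "features.csv")
    bpath = dirpath / "boundaries.geojson"
    bounds = _boundaries_from_geojson(bpath) if bpath.exists() else {}
    return CellLayer(matrix, cells, feats, bounds)


def _write_unit_layer(layer: UnitLayer, dirpath: Path) -> None:
    _write_matrix_layer(
        layer.matrix,
        {"units.csv": layer.unit_table, "features.csv": layer.feature_table},
        dirpath,
    )
    features = []
    for uid, ring_arr in layer.shapes.items():
        ring = np.asarray(ring_arr).tolist()
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"unit_id": str(uid)},
            }
        )
    with open(dirpath / "shapes.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "coordinate_unit": "micron", "features": features}, fh)


def _read_unit_layer(dirpath: Path) -> UnitLayer:
    matrix = _read_matrix(dirpath / "matrix.mtx")
    units = pd.read_csv(dirpath / "units.csv", dtype={"unit_id": str})
    feats = pd.read_csv(dirpath / "features.csv")
    with open(dirpath / "shapes.geojson") as fh:
        doc = json.load(fh)
    shapes = {
        str(f["properties"]["unit_id"]): as_ring(np.asarray(f["geometry"]["coordinates"][0], dtype=float))
        for f in doc.get("features", [])
    }
    return UnitLayer(matrix, units, feats, shapes)


# ---------------------------------------------------------------------------
# saveas / save / load
# ---------------------------------------------------------------------------

def saveas(sample: Sample, root: str | Path, overwrite: bool = False) -> dict:
    """Full write of a sample to a fresh project directory.

    Images and transcripts go under ``static/`` with SHA-256 digests
    recorded; everything else under ``variable/``. The manifest is written
    last, so a readable manifest implies a complete write. Refuses a
    non-empty target unless ``overwrite=True``.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise ProjectError(f"target {root} is not empty (pass overwrite=True)")
        shutil.rmtree(root)
    root.mkdir(parents=True, exist_ok=True)
    if sample.uid is None:
        from .experiment import mint_uid

        sample.uid = mint_uid()

    static = root / "static"
    variable = root / "variable"
    static_files: list[Path] = []
    inventory: dict = {"images": {}, "transcripts": None, "cells": [], "units": [],
                       "annotations": [], "regions": []}

    for name, img in sample.images.items():
        files = _write_image(img, static / "images", name)
        static_files += files
        inventory["images"][name] = {
            "path": str(files[0].relative_to(root)),
            "pixel_size": img.pixel_size,
            "channel_names": img.channel_names,
        }

    t = sample.transcripts_frame()
    if t is not None:
        validate_transcripts(t)
        static.mkdir(parents=True, exist_ok=True)
        tpath = static / "transcripts.parquet"
        t.to_parquet(tpath, index=False)
        static_files.append(tpath)
        inventory["transcripts"] = str(tpath.relative_to(root))

    _write_variable(sample, variable, inventory)

    manifest = {
        "format_version": FORMAT_VERSION,
        "uid": sample.uid,
        "created": _now(),
        "updated": _now(),
        "inventory": inventory,
        "static_checksums": {str(p.relative_to(root)): sha256_file(p) for p in static_files},
        "crop_offset_um": sample.metadata.get("crop_offset_um"),
    }
    with open(root / MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _write_variable(sample: Sample, variable: Path, inventory: dict) -> None:
    variable.mkdir(parents=True, exist_ok=True)
    for lname, layer in sample.cells.items():
        _write_cell_layer(layer, variable / "cells" / lname)
        inventory["cells"].append(lname)
    for lname, layer in sample.units.items():
        _write_unit_layer(layer, variable / "units" / lname)
        inventory["units"].append(lname)
    (variable / "annotations").mkdir(exist_ok=True)
    for name, pset in sample.annotations.items():
        export_annotations_geojson(pset, variable / "annotations" / f"{name}.geojson")
        inventory["annotations"].append(name)
    (variable / "regions").mkdir(exist_ok=True)
    for name, pset in sample.regions.items():
        export_annotations_geojson(pset, variable / "regions" / f"{name}.geojson")
        inventory["regions"].append(name)
    with open(variable / "metadata.json", "w") as fh:
        json.dump({"uid": sample.uid, "metadata": sample.metadata}, fh, default=str)


def save(sample: Sample, project: str | Path) -> dict:
    """Incremental save: rewrite only the variable subtree of an existing project.

    The project's manifest must exist and carry the sample's UID; static
    files are left untouched (their recorded digests remain valid).
    """
    project = Path(project)
    mpath = project / MANIFEST
    if not mpath.exists():
        raise ProjectError(f"{project} is not a project (no manifest); use saveas")
    with open(mpath) as fh:
        manifest = json.load(fh)
    if manifest["uid"] != sample.uid:
        raise ProjectError(
            f"project UID {manifest['uid']!r} does not match sample UID {sample.uid!r}"
        )
    variable = project / "variable"
    if variable.exists():
        shutil.rmtree(variable)
    inventory = manifest["inventory"]
    for key in ("cells", "units", "annotations", "regions"):
        inventory[key] = []
    _write_variable(sample, variable, inventory)
    manifest["updated"] = _now()
    manifest["crop_offset_um"] = sample.metadata.get("crop_offset_um")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _read_manifest(project: Path) -> dict:
    mpath = Path(project) / MANIFEST
    if not mpath.exists():
        raise ProjectError(f"{project} is not a project directory (no {MANIFEST})")
    with open(mpath) as fh:
        return json.load(fh)


def verify_static(project: str | Path) -> None:
    """Recompute static-file digests and raise :class:`ProjectError` on mismatch."""
    project = Path(project)
    manifest = _read_manifest(project)
    for rel, digest in manifest["static_checksums"].items():
        p = project / rel
        if not p.exists():
            raise ProjectError(f"static file missing: {rel}")
        if sha256_file(p) != digest:
            raise ProjectError(f"static file corrupted (checksum mismatch): {rel}")


def load_modality(project: str | Path, category: str, layer_name: str | None = None):
    """Load one data category from a project.

    Cells, units, annotations and regions are fully materialized; images
    and transcripts come back as lazy handles whose payload is read only
    on first access.
    """
    project = Path(project)
    manifest = _read_manifest(project)
    inv = manifest["inventory"]
    if category == "images":
        imgs = {
            name: _lazy_tiff_image(project / info["path"],
                                   {"pixel_size": info["pixel_size"],
                                    "channel_names": info["channel_names"], "name": name})
            for name, info in inv["images"].items()
        }
        if layer_name is not None:
            if layer_name not in imgs:
                raise KeyError(f"unknown image {layer_name!r}")
            return imgs[layer_name]
        return imgs
    if category == "transcripts":
        if inv["transcripts"] is None:
            return None
        return LazyTable(project / inv["transcripts"])
    if category == "cells":
        layers = {ln: _read_cell_layer(project / "variable" / "cells" / ln) for ln in inv["cells"]}
    elif category == "units":
        layers = {ln: _read_unit_layer(project / "variable" / "units" / ln) for ln in inv["units"]}
    elif category == "annotations":
        layers = {
            n: import_annotations_geojson(project / "variable" / "annotations" / f"{n}.geojson", "annotation")
            for n in inv["annotations"]
        }
    elif category == "regions":
        layers = {
            n: import_annotations_geojson(project / "variable" / "regions" / f"{n}.geojson", "region")
            for n in inv["regions"]
        }
    else:
        raise KeyError(f"unknown category {category!r}")
    if layer_name is not None:
        if layer_name not in layers:
            raise KeyError(f"unknown {category} layer {layer_name!r}")
        return layers[layer_name]
    return layers


def load_project(project: str | Path, verify: bool = False) -> Sample:
    """Open a project as a :class:`Sample` with lazy image/transcript handles.

    ``verify=True`` additionally checks the static-file digests recorded in
    the manifest (this reads every static file fully, defeating laziness,
    so it is opt-in).
    """
    project = Path(project)
    if verify:
        verify_static(project)
    manifest = _read_manifest(project)
    with open(project / "variable" / "metadata.json") as fh:
        meta_doc = json.load(fh)
    metadata = meta_doc.get("metadata", {})
    if isinstance(metadata.get("crop_offset_um"), list):
        metadata["crop_offset_um"] = tuple(metadata["crop_offset_um"])
    return Sample(
        uid=manifest["uid"],
        metadata=metadata,
        images=load_modality(project, "images"),
        transcripts=load_modality(project, "transcripts"),
        cells=load_modality(project, "cells"),
        units=load_modality(project, "units"),
        annotations=load_modality(project, "annotations"),
        regions=load_modality(project, "regions"),
    )


def saveas_experiment(experiment, root: str | Path, overwrite: bool = False) -> list[dict]:
    """Write an experiment: metadata table + one sample project per sample."""
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise ProjectError(f"target {root} is not empty (pass overwrite=True)")
        shutil.rmtree(root)
    root.mkdir(parents=True, exist_ok=True)
    experiment.metadata.to_csv(root / "metadata.csv", index=False)
    manifests = []
    for _, sample in experiment:
        manifests.append(saveas(sample, root / "samples" / sample.uid))
    with open(root / "experiment.json", "w") as fh:
        json.dump({"format_version": FORMAT_VERSION, "uids": experiment.uids()}, fh)
    return manifests


def load_experiment(root: str | Path):
    from .experiment import Experiment

    root = Path(root)
    with open(root / "experiment.json") as fh:
        doc = json.load(fh)
    meta = pd.read_csv(root / "metadata.csv", dtype={"uid": str})
    samples = [load_project(root / "samples" / uid) for uid in doc["uids"]]
    return Experiment(samples, meta)


# ---------------------------------------------------------------------------
# flat export (hierarchy -> keyed element groups)
# ---------------------------------------------------------------------------

def to_flat(sample: Sample, root: str | Path) -> dict[str, str]:
    """Flatten a sample into keyed element groups on disk.

    Elements are keyed ``<group>/<category>__<layer>`` with four groups:
    ``images`` (TIFF + metadata), ``points`` (transcripts), ``tables``
    (matrix + tables per layer) and ``shapes`` (boundaries, unit shapes,
    annotation/region sets as GeoJSON). ``from_flat`` restores the
    hierarchy losslessly for directories produced here. Returns the
    key → relative-path mapping; duplicate keys raise a naming error.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    elements: dict[str, str] = {}

    def _claim(key: str, rel: str):
        if key in elements:
            raise ValueError(f"flat key collision: {key!r}")
        elements[key] = rel

    for name, img in sample.images.items():
        _write_image(img, root / "images", name)
        _claim(f"images/{name}", f"images/{name}.tif")
    t = sample.transcripts_frame()
    if t is not None:
        (root / "points").mkdir(exist_ok=True)
        t.to_parquet(root / "points" / "transcripts.parquet", index=False)
        _claim("points/transcripts", "points/transcripts.parquet")
    for lname, layer in sample.cells.items():
        _write_cell_layer(layer, root / "tables" / f"cells__{lname}")
        _claim(f"tables/cells__{lname}", f"tables/cells__{lname}")
        if layer.boundaries:
            (root / "shapes").mkdir(exist_ok=True)
            _boundaries_to_geojson(layer.boundaries, root / "shapes" / f"cells__{lname}.geojson")
            _claim(f"shapes/cells__{lname}", f"shapes/cells__{lname}.geojson")
            # the boundaries file inside tables/ duplicates the shapes element
            (root / "tables" / f"cells__{lname}" / "boundaries.geojson").unlink()
    for lname, layer in sample.units.items():
        _write_unit_layer(layer, root / "tables" / f"units__{lname}")
        _claim(f"tables/units__{lname}", f"tables/units__{lname}")
        (root / "shapes").mkdir(exist_ok=True)
        (root / "tables" / f"units__{lname}" / "shapes.geojson").rename(
            root / "shapes" / f"units__{lname}.geojson"
        )
        _claim(f"shapes/units__{lname}", f"shapes/units__{lname}.geojson")
    (root / "shapes").mkdir(exist_ok=True)
    for name, pset in sample.annotations.items():
        export_annotations_geojson(pset, root / "shapes" / f"annotations__{name}.geojson")
        _claim(f"shapes/annotations__{name}", f"shapes/annotations__{name}.geojson")
    for name, pset in sample.regions.items():
        export_annotations_geojson(pset, root / "shapes" / f"regions__{name}.geojson")
        _claim(f"shapes/regions__{name}", f"shapes/regions__{name}.geojson")

    with open(root / "flat.json", "w") as fh:
        json.dump(
            {"uid": sample.uid, "metadata": sample.metadata, "elements": elements},
            fh,
            default=str,
        )
    return elements


def from_flat(root: str | Path) -> Sample:
    """Rebuild a :class:`Sample` from a directory written by :func:`to_flat`."""
    root = Path(root)
    with open(root / "flat.json") as fh:
        doc = json.load(fh)
    sample = Sample(uid=doc["uid"], metadata=doc.get("metadata", {}))
    for key, rel in doc["elements"].items():
        group, item = key.split("/", 1)
        if group == "images":
            with open(root / "images" / f"{item}.meta.json") as fh:
                meta = json.load(fh)
            sample.images[item] = _lazy_tiff_image(root / rel, meta)
        elif group == "points":
            sample.transcripts = LazyTable(root / rel)
        elif group == "tables" and item.startswith("cells__"):
            lname = item[len("cells__"):]
            layer = _read_cell_layer(root / rel)
            shp = root / "shapes" / f"cells__{lname}.geojson"
            if shp.exists():
                layer.boundaries = _boundaries_from_geojson(shp)
            sample.cells[lname] = layer
        elif group == "tables" and item.startswith("units__"):
            lname = item[len("units__"):]
            dirpath = root / rel
            matrix = _read_matrix(dirpath / "matrix.mtx")
            units = pd.read_csv(dirpath / "units.csv", dtype={"unit_id": str})
            feats = pd.read_csv(dirpath / "features.csv")
            with open(root / "shapes" / f"units__{lname}.geojson") as fh:
                sdoc = json.load(fh)
            shapes = {
                str(f["properties"]["unit_id"]): as_ring(
                    np.asarray(f["geometry"]["coordinates"][0], dtype=float)
                )
                for f in sdoc.get("features", [])
            }
            sample.units[lname] = UnitLayer(matrix, units, feats, shapes)
        elif group == "shapes" and item.startswith("annotations__"):
            name = item[len("annotations__"):]
            sample.annotations[name] = import_annotations_geojson(root / rel, "annotation")
        elif group == "shapes" and item.startswith("regions__"):
            name = item[len("regions__"):]
            sample.regions[name] = import_annotations_geojson(root / rel, "region")
        # shapes/cells__* handled together with their table element
    return sample
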