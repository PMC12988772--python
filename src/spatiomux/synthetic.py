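"""Synthetic fixture generator with known ground truth.

Produces fully populated samples and experiments so that every part of the
package — container operations, storage, registration, quantification and
the multi-sample analyses — is testable without downloading an accession.

What is emulated per sample:

* cell centroids by uniform sampling with minimum-distance thinning
  (dart throwing), so cells do not pile up;
* cell types laid out in vertical spatial bands (band widths proportional
  to the requested type fractions), giving annotations and regions
  non-trivial, verifiable contents;
* per-type expression profiles: one symmetric-Dirichlet base profile per
  type whose marker block is multiplied by a fold change and renormalized;
* per-cell counts: library size ~ lognormal (median 200 counts),
  counts ~ multinomial over the cell's type profile;
* transcripts: one point per counted molecule, Gaussian-scattered around
  the centroid (σ = 3 µm) and clipped to the cell disk, carrying the cell
  assignment;
* boundaries: jittered disk polygons (cellular) with concentric nuclear
  disks at 45 % radius;
* a rendered nuclear image: Gaussian blobs with per-nucleus amplitude and
  width variation plus Poisson noise;
* one annotation set labelling the type bands and one region set holding
  a 2×2 rectangle grid that tiles the extent (stand-in for TMA cores).

Everything is drawn from a single seeded generator per call, so outputs
are reproducible byte for byte under a fixed seed.
"""

from __future__ import annotations

import hashlib
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CellLayer, PixelImage, PolygonSet, Sample

__all__ = [
    "GroundTruth",
    "generate_sample",
    "generate_registration_pair",
    "generate_experiment",
    "generate_dge_pair",
    "sample_digest",
]


@dataclass
class GroundTruth:
    """Planted parameters behind one synthetic sample (or experiment)."""

    seed: int
    centroids: np.ndarray | None = None
    types: np.ndarray | None = None
    type_names: list[str] = field(default_factory=list)
    type_fractions: np.ndarray | None = None
    profiles: np.ndarray | None = None            # n_types × n_genes
    markers: dict = field(default_factory=dict)   # type name -> gene indices
    marker_fc: float = 1.0
    library_sizes: np.ndarray | None = None
    band_edges: np.ndarray | None = None
    region_names: list[str] = field(default_factory=list)
    transform: np.ndarray | None = None           # planted registration matrix
    conditions: list[str] = field(default_factory=list)
    de_genes: np.ndarray | None = None
    de_fold: float = 1.0
    per_sample: list = field(default_factory=list)


def _dart_throw(rng, n: int, lo: float, hi: float, min_dist: float, max_rounds: int = 60):
    """Uniform points in [lo, hi]² at pairwise distance >= min_dist."""
    accepted = np.empty((0, 2))
    for _ in range(max_rounds):
        need = n - len(accepted)
        if need <= 0:
            break
        cand = rng.uniform(lo, hi, size=(need * 3, 2))
        for p in cand:
            if len(accepted) >= n:
                break
            if len(accepted) == 0 or np.min(np.sum((accepted - p) ** 2, axis=1)) >= min_dist**2:
                accepted = np.vstack([accepted, p])
    if len(accepted) < n:
        raise RuntimeError(
            f"could not place {n} cells at min distance {min_dist:.1f} µm; "
            "lower n_cells or enlarge the image"
        )
    return accepted[:n]


def _disk_ring(rng, center: np.ndarray, radius: float, n_vertices: int = 16) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = radius * rng.uniform(0.9, 1.1, size=n_vertices)
    return np.column_stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)])


def _render_nuclei(rng, centroids_um: np.ndarray, image_px: int, pixel_size: float,
                   sigmas_um: np.ndarray | None = None) -> np.ndarray:
    """Gaussian-blob nuclear image with Poisson noise, uint8."""
    img = np.full((image_px, image_px), 4.0)
    n = len(centroids_um)
    amps = rng.uniform(90, 250, size=n)
    if sigmas_um is None:
        sigmas_um = rng.uniform(2.0, 4.5, size=n)
    for (x, y), amp, s_um in zip(centroids_um, amps, sigmas_um):
        cx, cy, sp = x / pixel_size, y / pixel_size, s_um / pixel_size
        half = int(np.ceil(3 * sp))
        r0, r1 = max(0, int(cy) - half), min(image_px, int(cy) + half + 1)
        c0, c1 = max(0, int(cx) - half), min(image_px, int(cx) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amp * np.exp(-(((xx + 0.5) - cx) ** 2 + ((yy + 0.5) - cy) ** 2) / (2 * sp**2))
    noisy = rng.poisson(img).astype(float)
    return np.clip(noisy, 0, 255).astype(np.uint8)


def generate_sample(
    n_cells: int = 500,
    n_genes: int = 100,
    n_types: int = 3,
    image_px: int = 1024,
    pixel_size: float = 0.5,
    marker_fc: float = 4.0,
    n_markers_per_type: int = 10,
    seed: int = 0,
    type_fractions=None,
    render_image: bool = True,
    profile_boost: tuple[np.ndarray, float] | None = None,
    min_dist: float | None = None,
) -> tuple[Sample, GroundTruth]:
    """Generate one synthetic sample with all six data categories populated.

    ``profile_boost=(gene_indices, fold)`` multiplies the given genes by
    ``fold`` in every type profile (before renormalization) — used to
    plant condition-specific differential expression at the experiment
    level while keeping counts and transcripts consistent.
    """
    if n_markers_per_type * n_types > n_genes:
        raise ValueError("n_markers_per_type * n_types must not exceed n_genes")
    rng = np.random.default_rng(seed)
    extent = image_px * pixel_size
    type_names = list(string.ascii_uppercase[:n_types])
    fractions = (
        np.full(n_types, 1.0 / n_types) if type_fractions is None
        else np.asarray(type_fractions, dtype=float)
    )
    fractions = fractions / fractions.sum()

    margin = min(8.0, extent / 16)
    if min_dist is None:
        min_dist = 0.35 * (extent - 2 * margin) / np.sqrt(n_cells)
    centroids = _dart_throw(rng, n_cells, margin, extent - margin, min_dist)

    # vertical bands with widths proportional to the type fractions
    edges = np.concatenate([[0.0], np.cumsum(fractions) * extent])
    band = np.clip(np.searchsorted(edges, centroids[:, 0], side="right") - 1, 0, n_types - 1)
    types = np.array([type_names[t] for t in band])

    # expression profiles: shared Dirichlet base, marker block boosted per type
    base = rng.dirichlet(np.ones(n_genes))
    profiles = np.tile(base, (n_types, 1))
    markers = {}
    for t in range(n_types):
        idx = np.arange(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        profiles[t, idx] *= marker_fc
        markers[type_names[t]] = idx
    if profile_boost is not None:
        boost_idx, boost_fold = profile_boost
        profiles[:, np.asarray(boost_idx, dtype=int)] *= boost_fold
    profiles /= profiles.sum(axis=1, keepdims=True)

    libs = np.maximum(1, np.round(rng.lognormal(np.log(200), 0.3, size=n_cells))).astype(int)
    matrix = np.empty((n_cells, n_genes), dtype=np.int64)
    for i in range(n_cells):
        matrix[i] = rng.multinomial(libs[i], profiles[band[i]])

    genes = [f"gene_{g:03d}" for g in range(n_genes)]
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    # radii capped by the packing distance so cellular disks (incl. the
    # 10% vertex jitter) never overlap and per-cell sums stay conservative
    r_hi = min(7.0, 0.43 * min_dist)
    r_lo = min(5.0, 0.32 * min_dist)
    radii = rng.uniform(r_lo, r_hi, size=n_cells)
    boundaries = {"cellular": {}, "nuclear": {}}
    for i, cid in enumerate(cell_ids):
        boundaries["cellular"][cid] = _disk_ring(rng, centroids[i], radii[i])
        boundaries["nuclear"][cid] = _disk_ring(rng, centroids[i], 0.45 * radii[i])

    cell_table = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "centroid_x": centroids[:, 0],
            "centroid_y": centroids[:, 1],
            "cell_type": types,
        }
    )
    layer = CellLayer(matrix, cell_table, pd.DataFrame({"feature": genes}), boundaries)

    # transcripts: one point per counted molecule, clipped to the cell disk
    cell_idx = np.repeat(np.arange(n_cells), matrix.sum(axis=1))
    gene_idx = np.concatenate([np.repeat(np.arange(n_genes), matrix[i]) for i in range(n_cells)])
    offsets = rng.normal(0, 3.0, size=(len(cell_idx), 2))
    norms = np.linalg.norm(offsets, axis=1)
    cap = radii[cell_idx]
    over = norms > cap
    offsets[over] *= (cap[over] / norms[over])[:, None]
    pts = centroids[cell_idx] + offsets
    transcripts = pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "gene": np.asarray(genes)[gene_idx],
            "quality": rng.uniform(20, 40, size=len(pts)),
            "cell_id": np.asarray(cell_ids)[cell_idx],
        }
    )

    sample = Sample(metadata={}, transcripts=transcripts, cells={"default": layer})

    if render_image:
        nuc_sigma = 0.45 * radii / 1.5
        img = _render_nuclei(rng, centroids, image_px, pixel_size, sigmas_um=nuc_sigma)
        sample.images["nuclei"] = PixelImage(
            img, pixel_size=pixel_size, channel_names=["DAPI"], name="nuclei"
        )

    bands = PolygonSet(scope="annotation")
    for t in range(n_types):
        x0, x1 = edges[t], edges[t + 1]
        bands.add(
            f"band_{type_names[t]}",
            type_names[t],
            [(x0, 0.0), (x1, 0.0), (x1, extent), (x0, extent)],
        )
    sample.annotations["bands"] = bands

    grid = PolygonSet(scope="region")
    half = extent / 2
    region_names = []
    for i in range(2):
        for j in range(2):
            name = f"core_r{i}c{j}"
            region_names.append(name)
            grid.add(
                name,
                "core",
                [(j * half, i * half), ((j + 1) * half, i * half),
                 ((j + 1) * half, (i + 1) * half), (j * half, (i + 1) * half)],
            )
    sample.regions["grid"] = grid

    truth = GroundTruth(
        seed=seed,
        centroids=centroids,
        types=types,
        type_names=type_names,
        type_fractions=fractions,
        profiles=profiles,
        markers=markers,
        marker_fc=marker_fc,
        library_sizes=libs,
        band_edges=edges,
        region_names=region_names,
    )
    return sample, truth


def _planted_affine(rotation_deg: float, scale: float, shift_px, center_px: float) -> np.ndarray:
    th = np.deg2rad(rotation_deg)
    rs = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c = np.array([center_px, center_px])
    t = np.asarray(shift_px, dtype=float) + c - rs @ c
    m = np.eye(3)
    m[:2, :2] = rs
    m[:2, 2] = t
    return m


def generate_registration_pair(
    seed: int = 0,
    rotation_deg: float = 0.0,
    scale: float = 1.0,
    shift_px=(0.0, 0.0),
    image_px: int = 1024,
    pixel_size: float = 0.5,
    n_cells: int | None = None,
) -> tuple[PixelImage, PixelImage, np.ndarray]:
    """A (fixed, moving, planted matrix) triple for registration tests.

    The fixed image is a rendered nuclear stain; the moving image is the
    fixed image warped by the planted affine (rotation and scale about the
    image center, then a pixel shift) plus a mild intensity perturbation
    (gamma 1.1, Gaussian noise σ = 2/255). The returned matrix maps
    moving pixel coordinates to fixed pixel coordinates.
    """
    if abs(rotation_deg) > 45:
        raise ValueError("|rotation_deg| must be <= 45")
    if not 0.5 <= scale <= 2.0:
        raise ValueError("scale must lie in [0.5, 2]")
    from skimage.transform import ProjectiveTransform, warp

    rng = np.random.default_rng(seed)
    extent = image_px * pixel_size
    if n_cells is None:
        n_cells = max(60, int(round(500 * (image_px / 1024) ** 2)))
    margin = min(8.0, extent / 16)
    min_dist = 0.35 * (extent - 2 * margin) / np.sqrt(n_cells)
    cents = _dart_throw(rng, n_cells, margin, extent - margin, min_dist)
    fixed = _render_nuclei(rng, cents, image_px, pixel_size)

    planted = _planted_affine(rotation_deg, scale, shift_px, center_px=image_px / 2)
    moving = warp(
        fixed.astype(float) / 255.0,
        inverse_map=ProjectiveTransform(matrix=planted),
        order=1,
        cval=0.0,
    )
    moving = np.power(np.clip(moving, 0, 1), 1.1)
    moving = moving + rng.normal(0, 2 / 255, size=moving.shape)
    moving8 = np.clip(moving * 255, 0, 255).astype(np.uint8)

    fixed_img = PixelImage(fixed, pixel_size=pixel_size, channel_names=["DAPI"], name="nuclei")
    moving_img = PixelImage(moving8, pixel_size=pixel_size, channel_names=["HE"], name="histology")
    return fixed_img, moving_img, planted


def generate_experiment(
    n_samples: int = 5,
    conditions: tuple[str, ...] = ("treated", "control"),
    seed: int = 0,
    n_cells: int = 500,
    n_genes: int = 100,
    image_px: int = 1024,
    render_images: bool = False,
    de_fold: float = 3.0,
    n_de_genes: int = 10,
    treated_shift: float = 0.15,
):
    """Synthetic multi-sample experiment with condition structure.

    Conditions are assigned round-robin. "treated" samples get (i) a
    composition shift: +``treated_shift`` on the type-A fraction, the
    remaining types scaled down proportionally; and (ii) a planted
    differentially expressed gene set (the last ``n_de_genes`` genes,
    multiplied by ``de_fold`` in every type profile before renormalization).
    """
    from .experiment import Experiment

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    de_genes = np.arange(n_genes - n_de_genes, n_genes)
    exp = Experiment()
    truths = []
    cond_list = []
    for i in range(n_samples):
        condition = conditions[i % len(conditions)]
        cond_list.append(condition)
        base = np.full(3, 1.0 / 3)
        if condition == "treated":
            fa = base[0] + treated_shift
            fractions = np.concatenate([[fa], base[1:] * (1 - fa) / (1 - base[0])])
        else:
            fractions = base
        child_seed = int(rng.integers(0, 2**31 - 1))
        boost = (de_genes, de_fold) if condition == "treated" and de_fold != 1.0 else None
        sample, truth = generate_sample(
            n_cells=n_cells,
            n_genes=n_genes,
            image_px=image_px,
            seed=child_seed,
            type_fractions=fractions,
            render_image=render_images,
            profile_boost=boost,
        )
        sample.uid = f"s{i:02d}"
        truths.append(truth)
        exp.add(sample, {"condition": condition, "donor": f"donor_{i // 2}"})
    truth = GroundTruth(
        seed=seed, conditions=cond_list, de_genes=de_genes, de_fold=de_fold,
        per_sample=truths,
    )
    return exp, truth


def generate_dge_pair(
    n_cells: int = 200,
    n_genes: int = 100,
    n_markers: int = 10,
    fold: float = 4.0,
    null: bool = False,
    seed: int = 13,
):
    """Two cell populations for differential-expression calibration tests.

    Per-gene baseline rates come from a symmetric-Dirichlet profile scaled
    to a mean library of 200 counts; each cell draws counts as independent
    Poissons of (rate × lognormal library factor). Group A multiplies the
    marker genes' rates by ``fold`` (no renormalization, so the planted
    fold change is exactly ``fold`` in the markers and exactly 1
    elsewhere); ``null=True`` makes both groups identical. Markers are
    the ``n_markers`` genes with baseline expression closest to the
    profile median, i.e. planted at representative abundance rather than
    in the extreme tails. Returns ``(layer_A, layer_B, marker_indices)``.
    """
    rng = np.random.default_rng(seed)
    rates = rng.dirichlet(np.ones(n_genes)) * 200.0
    markers = np.sort(np.argsort(np.abs(rates - np.median(rates)), kind="stable")[:n_markers])
    rates_a = rates.copy()
    if not null:
        rates_a[markers] *= fold

    genes = [f"gene_{g:03d}" for g in range(n_genes)]

    def _population(gene_rates, tag):
        libs = rng.lognormal(0.0, 0.3, size=n_cells)
        matrix = rng.poisson(gene_rates[None, :] * libs[:, None])
        table = pd.DataFrame(
            {
                "cell_id": [f"{tag}_{i:05d}" for i in range(n_cells)],
                "centroid_x": rng.uniform(0, 100, n_cells),
                "centroid_y": rng.uniform(0, 100, n_cells),
            }
        )
        return CellLayer(matrix, table, pd.DataFrame({"feature": genes}))

    return _population(rates_a, "a"), _population(rates, "b"), markers


def sample_digest(sample: Sample) -> str:
    """SHA-256 digest over a sample's array contents (determinism checks)."""
    h = hashlib.sha256()
    for name in sorted(sample.images):
        h.update(name.encode())
        h.update(np.ascontiguousarray(sample.images[name].pixels).tobytes())
    t = sample.transcripts_frame()
    if t is not None:
        h.update(pd.util.hash_pandas_object(t, index=False).to_numpy().tobytes())
    for lname in sorted(sample.cells):
        layer = sample.cells[lname]
        h.update(lname.encode())
        h.update(np.ascontiguousarray(layer.dense_matrix()).tobytes())
        h.update(pd.util.hash_pandas_object(layer.cell_table, index=False).to_numpy().tobytes())
        for kind in sorted(layer.boundaries):
            for cid in sorted(layer.boundaries[kind]):
                h.update(np.ascontiguousarray(layer.boundaries[kind][cid]).tobytes())
    for attr in ("annotations", "regions"):
        for name, pset in sorted(getattr(sample, attr).items()):
            for e in pset:
                h.update(e.name.encode())
                h.update(e.class_label.encode())
                h.update(np.ascontiguousarray(e.vertices).tobytes())
    return h.hexdigest()
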