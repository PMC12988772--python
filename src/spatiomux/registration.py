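"""Automated histology-to-fluorescence image registration.

Aligns a post-run histology image (moving) to the nuclear fluorescence
image acquired during the spatial omics run (fixed), which is already in
the omics coordinate frame. The pipeline is feature-based:

1. preprocess: grayscale, optional intensity inversion (bright-field
   histology has dark nuclei; inverting makes nuclei bright in both
   modalities), downscale so the longest side is at most a cap,
   percentile contrast normalization to 8-bit;
2. SIFT keypoint detection and 128-d description on both images;
3. nearest-neighbour descriptor matching (k=2) with Lowe's ratio test;
4. RANSAC estimation of an affine (default) or perspective transform,
   followed by a least-squares refit on the inliers.

The returned transform maps moving full-resolution pixel coordinates
(x, y) = (column, row) into the fixed full-resolution pixel frame, and is
reported together with QC metrics (keypoint/match/inlier counts, mean
reprojection error over inliers, downscale factors). A result whose
inlier fraction falls below ``MIN_INLIER_FRACTION`` is flagged, not
rejected — the caller decides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktf
from skimage.color import rgb2gray
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac

from ._exceptions import RegistrationError
from .core import PixelImage

__all__ = [
    "RegistrationResult",
    "preprocess_for_features",
    "detect_and_describe",
    "match_descriptors_ratio",
    "estimate_transform",
    "register_pair",
    "apply_transform_image",
    "transform_points",
]

DOWNSCALE_CAP = 4096        # px, longest side before feature detection
LOWE_RATIO = 0.75
RANSAC_THRESHOLD = 5.0      # px, on the downscaled frame
MIN_INLIER_FRACTION = 0.2
MIN_INLIERS = 10            # consensus below this is flagged regardless of fraction


@dataclass
class RegistrationResult:
    """Estimated transform plus QC metrics.

    ``transform`` is a 3×3 matrix acting on homogeneous (x, y, 1) moving
    full-resolution pixel coordinates; for ``kind == "affine"`` its last
    row is (0, 0, 1).
    """

    transform: np.ndarray
    kind: str
    n_keypoints_fixed: int = 0
    n_keypoints_moving: int = 0
    n_matches: int = 0
    n_inliers: int = 0
    mean_reprojection_error: float = float("nan")
    downscale_factor: float = 1.0
    flagged: bool = False
    notes: str = ""

    def __post_init__(self):
        self.transform = np.asarray(self.transform, dtype=float)
        if self.transform.shape != (3, 3):
            raise ValueError("transform must be 3x3")
        if self.n_inliers > self.n_matches:
            raise ValueError("n_inliers cannot exceed n_matches")
        if self.kind == "affine" and not np.allclose(self.transform[2], [0, 0, 1]):
            raise ValueError("affine transform must have last row (0, 0, 1)")

    @property
    def inlier_fraction(self) -> float:
        return self.n_inliers / self.n_matches if self.n_matches else 0.0

    def qc_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_keypoints_fixed": self.n_keypoints_fixed,
            "n_keypoints_moving": self.n_keypoints_moving,
            "n_matches": self.n_matches,
            "n_inliers": self.n_inliers,
            "inlier_fraction": self.inlier_fraction,
            "mean_reprojection_error": self.mean_reprojection_error,
            "downscale_factor": self.downscale_factor,
            "flagged": self.flagged,
            "notes": self.notes,
        }


def _as_array(image) -> np.ndarray:
    return image.pixels if isinstance(image, PixelImage) else np.asarray(image)


def preprocess_for_features(
    image, cap: int = DOWNSCALE_CAP, invert: bool = False
) -> tuple[np.ndarray, int]:
    """Condition an image for feature detection.

    Returns a single-channel 8-bit image and the integer downscale factor
    applied (1 if the image already fits the cap). RGB input is converted
    to luminance; ``invert`` flips intensities (for bright-field
    histology). Contrast is stretched between the 1st and 99th
    percentiles. A constant image yields all zeros — downstream detection
    then finds no keypoints, which callers treat as a failure with QC.
    """
    arr = _as_array(image)
    if arr.ndim == 3:
        arr = rgb2gray(arr[..., :3]) if arr.shape[2] >= 3 else arr[..., 0]
    arr = arr.astype(float)
    factor = max(1, math.ceil(max(arr.shape) / cap))
    if factor > 1:
        arr = sktf.downscale_local_mean(arr, (factor, factor))
    lo, hi = np.percentile(arr, [1, 99])
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.uint8), factor
    arr = np.clip((arr - lo) / (hi - lo), 0, 1)
    if invert:
        arr = 1.0 - arr
    return (arr * 255).astype(np.uint8), factor


def detect_and_describe(image8: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SIFT keypoints and 128-d descriptors.

    Keypoints are returned as (x, y) = (column, row) coordinates. A
    featureless image yields empty arrays rather than an error.
    """
    if image8.ndim != 2 or image8.dtype != np.uint8:
        raise ValueError("expected a single-channel 8-bit image")
    sift = SIFT()
    try:
        sift.detect_and_extract(image8)
    except RuntimeError:  # skimage raises when no keypoints survive
        return np.empty((0, 2)), np.empty((0, 128), dtype=np.uint8)
    kp_xy = sift.keypoints[:, ::-1].astype(float)  # (row, col) -> (x, y)
    return kp_xy, sift.descriptors


def match_descriptors_ratio(
    desc_fixed: np.ndarray, desc_moving: np.ndarray, ratio: float = LOWE_RATIO
) -> np.ndarray:
    """Nearest-neighbour matches surviving Lowe's ratio test.

    Returns an (n, 2) index array of (fixed, moving) descriptor pairs. A
    match is kept iff the best neighbour's distance is below ``ratio``
    times the second best (cross-checked both ways); with fewer than two
    candidate neighbours the ratio test cannot run and the match is
    dropped.
    """
    if len(desc_fixed) == 0 or len(desc_moving) == 0:
        return np.empty((0, 2), dtype=int)
    if min(len(desc_fixed), len(desc_moving)) < 2:
        return np.empty((0, 2), dtype=int)
    return match_descriptors(
        desc_fixed.astype(float),
        desc_moving.astype(float),
        cross_check=True,
        max_ratio=ratio,
    )


def _fit_transform(tclass, src: np.ndarray, dst: np.ndarray):
    """Least-squares fit across skimage API generations; None on failure."""
    if hasattr(tclass, "from_estimate"):
        tf = tclass.from_estimate(src, dst)
        return tf if tf else None
    tf = tclass()
    return tf if tf.estimate(src, dst) else None


def _transform_class(kind: str):
    if kind == "affine":
        return sktf.AffineTransform, 3
    if kind == "perspective":
        return sktf.ProjectiveTransform, 4
    raise ValueError(f"kind must be 'affine' or 'perspective', got {kind!r}")


def estimate_transform(
    src_moving: np.ndarray,
    dst_fixed: np.ndarray,
    kind: str = "affine",
    ransac_threshold_px: float = RANSAC_THRESHOLD,
    seed: int = 0,
    max_trials: int = 2000,
) -> RegistrationResult:
    """RANSAC fit of the transform mapping matched moving points onto fixed.

    Point sets are matched pairs in (x, y) pixel coordinates of whatever
    frame they live in (callers rescale the matrix afterwards if needed).
    After RANSAC the model is refit by least squares on the inlier set;
    the mean reprojection error is computed over those inliers.
    """
    src = np.asarray(src_moving, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst_fixed, dtype=float).reshape(-1, 2)
    tclass, min_samples = _transform_class(kind)
    if len(src) != len(dst):
        raise ValueError("src and dst must pair up")
    if len(src) < min_samples:
        raise RegistrationError(
            f"{len(src)} matches but {kind} needs at least {min_samples}",
            stage="estimate",
            counts={"n_matches": len(src)},
        )
    if len(src) == min_samples:
        model = _fit_transform(tclass, src, dst)
        if model is None:
            raise RegistrationError("degenerate minimal sample", stage="estimate",
                                    counts={"n_matches": len(src)})
        inliers = np.ones(len(src), dtype=bool)
    else:
        model, inliers = ransac(
            (src, dst),
            tclass,
            min_samples=min_samples,
            residual_threshold=ransac_threshold_px,
            max_trials=max_trials,
            rng=seed,
        )
        if model is None or inliers is None or inliers.sum() < min_samples:
            raise RegistrationError(
                "RANSAC found no consensus", stage="estimate",
                counts={"n_matches": len(src)},
            )
        refit = _fit_transform(tclass, src[inliers], dst[inliers])
        if refit is not None:
            model = refit
    residuals = np.linalg.norm(model(src[inliers]) - dst[inliers], axis=1)
    return RegistrationResult(
        transform=np.asarray(model.params, dtype=float),
        kind=kind,
        n_matches=len(src),
        n_inliers=int(inliers.sum()),
        mean_reprojection_error=float(residuals.mean()) if len(residuals) else float("nan"),
    )


def register_pair(
    fixed,
    moving,
    kind: str = "affine",
    ratio: float = LOWE_RATIO,
    ransac_threshold_px: float = RANSAC_THRESHOLD,
    cap: int = DOWNSCALE_CAP,
    invert_moving: bool = False,
    seed: int = 0,
) -> RegistrationResult:
    """Full registration pipeline: preprocess → detect → match → estimate.

    The result maps moving full-resolution pixels into the fixed
    full-resolution pixel frame. Failures at any stage raise
    :class:`RegistrationError` carrying the stage name and the QC counts
    collected so far; low-consensus successes are returned flagged.
    """
    fixed8, f_fixed = preprocess_for_features(fixed, cap=cap)
    moving8, f_moving = preprocess_for_features(moving, cap=cap, invert=invert_moving)

    kp_f, desc_f = detect_and_describe(fixed8)
    kp_m, desc_m = detect_and_describe(moving8)
    counts = {"n_keypoints_fixed": len(kp_f), "n_keypoints_moving": len(kp_m)}
    if len(kp_f) == 0 or len(kp_m) == 0:
        raise RegistrationError("no keypoints detected", stage="detect", counts=counts)

    matches = match_descriptors_ratio(desc_f, desc_m, ratio=ratio)
    counts["n_matches"] = len(matches)
    _, min_samples = _transform_class(kind)
    if len(matches) < min_samples:
        raise RegistrationError(
            f"only {len(matches)} ratio-test matches", stage="match", counts=counts
        )

    result = estimate_transform(
        kp_m[matches[:, 1]], kp_f[matches[:, 0]],
        kind=kind, ransac_threshold_px=ransac_threshold_px, seed=seed,
    )
    # rescale the matrix from downscaled to full-resolution coordinates
    s_f = np.diag([f_fixed, f_fixed, 1.0])
    s_m_inv = np.diag([1.0 / f_moving, 1.0 / f_moving, 1.0])
    full = s_f @ result.transform @ s_m_inv
    if kind == "affine":
        full[2] = (0.0, 0.0, 1.0)

    out = RegistrationResult(
        transform=full,
        kind=kind,
        n_keypoints_fixed=len(kp_f),
        n_keypoints_moving=len(kp_m),
        n_matches=result.n_matches,
        n_inliers=result.n_inliers,
        mean_reprojection_error=result.mean_reprojection_error * f_fixed,
        downscale_factor=float(f_fixed),
    )
    if out.inlier_fraction < MIN_INLIER_FRACTION or out.n_inliers < MIN_INLIERS:
        out.flagged = True
        out.notes = (
            f"weak consensus: {out.n_inliers} inliers "
            f"(fraction {out.inlier_fraction:.2f}); thresholds: "
            f"fraction {MIN_INLIER_FRACTION}, count {MIN_INLIERS}"
        )
    return out


def apply_transform_image(moving, transform: np.ndarray, output_shape: tuple[int, int]):
    """Resample the moving image into the fixed frame (bilinear, 0 outside).

    ``transform`` maps moving (x, y) pixels to fixed (x, y) pixels; the
    warp therefore samples the moving image at ``transform⁻¹`` of each
    output pixel. Returns a :class:`PixelImage` when given one, else an
    array.
    """
    matrix = np.asarray(transform, dtype=float)
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("singular transform cannot be applied")
    arr = _as_array(moving)
    tf = sktf.ProjectiveTransform(matrix=matrix)
    warped = sktf.warp(
        arr.astype(float),
        inverse_map=tf.inverse,
        output_shape=output_shape,
        order=1,
        cval=0.0,
        preserve_range=True,
    )
    warped = warped.astype(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else warped
    if isinstance(moving, PixelImage):
        return PixelImage(
            warped, pixel_size=moving.pixel_size,
            channel_names=list(moving.channel_names), name=f"{moving.name}_registered",
        )
    return warped


def transform_points(points: np.ndarray, transform: np.ndarray) -> np.ndarray:
    """Apply a 3×3 homogeneous transform to (n, 2) points.

    Points whose homogeneous weight collapses to ~0 under a perspective
    transform are flagged invalid by returning NaN coordinates.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    matrix = np.asarray(transform, dtype=float)
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("singular transform")
    hom = np.column_stack([pts, np.ones(len(pts))])
    mapped = hom @ matrix.T
    w = mapped[:, 2]
    bad = np.abs(w) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        out = mapped[:, :2] / w[:, None]
    out[bad] = np.nan
    return out
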