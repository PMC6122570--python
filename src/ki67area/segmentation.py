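"""Ki67-positive / Ki67-negative nucleus-pixel segmentation.

The segmenter avoids per-nucleus detection entirely.  It works in three
stages: (1) k-means clustering of RGB pixels into three clusters
(background, hematoxylin-blue, DAB-brown); (2) a color transform built
in CIE L*a*b* that projects every pixel onto the hematoxylin-to-DAB axis
in the (a*, b*) chroma plane; (3) maximum-entropy (Kapur) thresholding
of the projected nucleus pixels to split them into positive and
negative.

A two-step variant guards against the failure mode of stain-free
images: a presence check using precomputed cluster centroids and a
precomputed color transform (derived once from an independent
calibration set) decides whether the image contains any DAB at all.
Only if it does are the image-specific centroids and transform
recomputed; otherwise the positive mask is forced empty and negative
nuclei are taken from the hematoxylin side of the precomputed
projection, so blue nuclei are never relabeled as positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage import color as _skcolor
from skimage.morphology import remove_small_objects
from sklearn.cluster import KMeans

__all__ = [
    "ClusterModel",
    "ColorTransform",
    "SegmentationMasks",
    "SegmentationConfig",
    "PrecomputedModel",
    "DegenerateClusterError",
    "ConstantInputError",
    "rgb_to_lab",
    "cluster_pixels",
    "cluster_pixel_array",
    "derive_color_transform",
    "kapur_threshold",
    "detect_positive_presence",
    "segment_roi",
    "load_default_precomputed",
]

ROLES = ("background", "hematoxylin", "dab")


class DegenerateClusterError(ValueError):
    """Image has too few distinct colors to form the requested clusters."""


class ConstantInputError(ValueError):
    """Thresholding a sample with fewer than two distinct values."""


def rgb_to_lab(rgb) -> np.ndarray:
    """Convert 8-bit sRGB values to CIE L*a*b* (D65 white point).

    Accepts a single (r, g, b) triple or an array with a trailing axis of
    length 3; values must lie in [0, 255].  L* is in [0, 100].
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected trailing axis of length 3")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    return _skcolor.rgb2lab(arr / 255.0)


@dataclass
class ClusterModel:
    """Three role-tagged RGB cluster centroids (background / H / DAB)."""

    centroids: np.ndarray  # (3, 3) RGB
    roles: tuple[str, str, str]

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (3, 3):
            raise ValueError("need exactly 3 RGB centroids")
        if sorted(self.roles) != sorted(ROLES):
            raise ValueError(f"roles must be a permutation of {ROLES}")
        d = self.centroids[:, None, :] - self.centroids[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        if np.any(dist[~np.eye(3, dtype=bool)] < 1e-9):
            raise DegenerateClusterError("coincident cluster centroids")

    def centroid(self, role: str) -> np.ndarray:
        return self.centroids[self.roles.index(role)]

    def assign(self, pixels: np.ndarray) -> np.ndarray:
        """Index of the nearest centroid for each RGB pixel (flat last axis)."""
        px = np.asarray(pixels, dtype=float).reshape(-1, 3)
        d2 = ((px[:, None, :] - self.centroids[None, :, :]) ** 2).sum(-1)
        return np.argmin(d2, axis=1)

    def to_dict(self) -> dict:
        return {"centroids": self.centroids.tolist(), "roles": list(self.roles)}

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(np.asarray(d["centroids"]), tuple(d["roles"]))


@dataclass
class ColorTransform:
    """Linear map on L*a*b* whose first component is the thresholding axis.

    The projection axis is the unit vector from the hematoxylin centroid
    to the DAB centroid in the (a*, b*) chroma plane; L* is excluded so
    staining intensity does not masquerade as stain identity.
    """

    matrix: np.ndarray  # (3, 3), applied to (L*, a*, b*)
    projection_axis: np.ndarray  # (3,), unit norm, zero L* component

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.projection_axis = np.asarray(self.projection_axis, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite transform matrix")
        if abs(np.linalg.norm(self.projection_axis) - 1.0) > 1e-8:
            raise ValueError("projection axis must have unit norm")

    def project(self, lab: np.ndarray) -> np.ndarray:
        return np.tensordot(np.asarray(lab, dtype=float), self.projection_axis, axes=([-1], [0]))

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "projection_axis": self.projection_axis.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColorTransform":
        return cls(np.asarray(d["matrix"]), np.asarray(d["projection_axis"]))


@dataclass
class SegmentationMasks:
    """Disjoint positive / negative nucleus-pixel masks plus provenance."""

    positive_mask: np.ndarray
    negative_mask: np.ndarray
    threshold_value: float
    used_precomputed: bool

    @property
    def positive_px(self) -> int:
        return int(self.positive_mask.sum())

    @property
    def negative_px(self) -> int:
        return int(self.negative_mask.sum())


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmenter.

    min_positive_px is the pixel count (after small-object removal, about
    a quarter of a small nucleus) above which the presence check declares
    the image DAB-positive; a literal one-pixel rule would be noise
    fragile.  l_background is an L* guard excluding near-white pixels
    from the nucleus set regardless of cluster assignment.
    """

    seed: int = 0
    subsample: int = 4
    n_bins: int = 256
    min_positive_px: int = 50
    min_area: int = 30
    l_background: float = 90.0


def cluster_pixel_array(
    pixels: np.ndarray, k: int = 3, seed: int = 0
) -> ClusterModel:
    """K-means on an (n, 3) RGB pixel array with deterministic seeding.

    Initial centers come from farthest-point traversal started at pixel
    index 0, so the optimisation is reproducible for a fixed input.
    Roles are tagged from the centroids' L*a*b* coordinates: highest L*
    is background; of the remaining two, the larger b* (yellow/brown
    direction) is DAB, the other hematoxylin.
    """
    px = np.asarray(pixels, dtype=float).reshape(-1, 3)
    if px.shape[0] < k or np.unique(px, axis=0).shape[0] < k:
        raise DegenerateClusterError(
            f"need at least {k} distinct colors to form {k} clusters"
        )
    init = [px[0]]
    d2 = ((px - init[0]) ** 2).sum(1)
    for _ in range(k - 1):
        init.append(px[int(np.argmax(d2))])
        d2 = np.minimum(d2, ((px - init[-1]) ** 2).sum(1))
    km = KMeans(n_clusters=k, init=np.array(init), n_init=1, random_state=seed)
    km.fit(px)
    centroids = km.cluster_centers_

    labs = rgb_to_lab(np.clip(centroids, 0, 255))
    roles = [""] * k
    bg = int(np.argmax(labs[:, 0]))
    roles[bg] = "background"
    rest = [i for i in range(k) if i != bg]
    dab = rest[int(np.argmax(labs[rest, 2]))]
    hem = [i for i in rest if i != dab][0]
    roles[dab] = "dab"
    roles[hem] = "hematoxylin"
    return ClusterModel(centroids, tuple(roles))


def cluster_pixels(image: np.ndarray, k: int = 3, seed: int = 0, subsample: int = 4) -> ClusterModel:
    """Cluster the RGB pixels of an image (subsampled for speed)."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    px = image.reshape(-1, 3)[::subsample]
    return cluster_pixel_array(px, k=k, seed=seed)


def derive_color_transform(model: ClusterModel) -> ColorTransform:
    """Build the hematoxylin-to-DAB chroma projection from a cluster model."""
    lab_h = rgb_to_lab(np.clip(model.centroid("hematoxylin"), 0, 255))
    lab_d = rgb_to_lab(np.clip(model.centroid("dab"), 0, 255))
    d = lab_d[1:] - lab_h[1:]
    norm = float(np.linalg.norm(d))
    # well-stained H-DAB centroids sit ~40 chroma units apart; below half a
    # unit the axis direction is numerically meaningless
    if norm < 0.5:
        raise DegenerateClusterError("hematoxylin and DAB centroids coincide in chroma")
    u = d / norm
    matrix = np.array([
        [0.0, u[0], u[1]],   # stain-identity axis (what gets thresholded)
        [0.0, -u[1], u[0]],  # orthogonal chroma residual
        [1.0, 0.0, 0.0],     # lightness passthrough
    ])
    return ColorTransform(matrix, np.array([0.0, u[0], u[1]]))


def kapur_threshold(values, n_bins: int = 256) -> float:
    """Maximum-entropy threshold of a 1-D sample (Kapur's criterion).

    The sample is histogrammed into n_bins uniform bins over its min-max
    range; the returned cut maximizes the sum of Shannon entropies of
    the two partitions, with ties broken toward the lower threshold.
    The value is returned on the original scale (an interior bin edge).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or v.max() == v.min():
        raise ConstantInputError("need at least two distinct values to threshold")
    hist, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    p = hist / hist.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_p = np.cumsum(p)
    cum_h = -np.cumsum(plogp)
    h_tot = cum_h[-1]
    s = cum_p[:-1]  # mass below each interior cut
    hb = cum_h[:-1]
    valid = (s > 1e-12) & (s < 1.0 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.log(s) + hb / s + np.log1p(-s) + (h_tot - hb) / (1.0 - s)
    psi = np.where(valid, psi, -np.inf)
    t = int(np.argmax(psi))  # argmax returns the first (lowest) maximizer
    return float(edges[t + 1])


@dataclass
class PrecomputedModel:
    """Centroids + transform computed once from an independent calibration set.

    presence_threshold is the midpoint of the projected hematoxylin and
    DAB centroids on the precomputed axis: a pixel beyond it is on the
    DAB side of the stain-identity axis.
    """

    cluster_model: ClusterModel
    transform: ColorTransform
    presence_threshold: float

    def to_json(self, path: str | Path) -> None:
        d = self.cluster_model.to_dict()
        d["transform"] = self.transform.matrix.tolist()
        d["projection_axis"] = self.transform.projection_axis.tolist()
        d["presence_threshold"] = self.presence_threshold
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PrecomputedModel":
        d = json.loads(Path(path).read_text())
        model = ClusterModel(np.asarray(d["centroids"]), tuple(d["roles"]))
        transform = ColorTransform(
            np.asarray(d["transform"]), np.asarray(d["projection_axis"])
        )
        return cls(model, transform, float(d["presence_threshold"]))

    @classmethod
    def from_cluster_model(cls, model: ClusterModel) -> "PrecomputedModel":
        transform = derive_color_transform(model)
        ph = transform.project(rgb_to_lab(np.clip(model.centroid("hematoxylin"), 0, 255)))
        pd_ = transform.project(rgb_to_lab(np.clip(model.centroid("dab"), 0, 255)))
        return cls(model, transform, float((ph + pd_) / 2.0))


def load_default_precomputed() -> PrecomputedModel:
    """Shipped default matrices, derived from the bundled synthetic calibration set."""
    path = resources.files("ki67area").joinpath("data/precomputed_hdab.json")
    return PrecomputedModel.from_json(str(path))


def _nucleus_mask(
    image: np.ndarray,
    lab: np.ndarray,
    model: ClusterModel,
    l_background: float,
) -> np.ndarray:
    """Pixels assigned to a stain cluster and not near-white."""
    assign = model.assign(image.reshape(-1, 3)).reshape(image.shape[:2])
    bg = model.roles.index("background")
    return (assign != bg) & (lab[..., 0] <= l_background)


def detect_positive_presence(
    image: np.ndarray,
    precomputed: PrecomputedModel | None = None,
    min_positive_px: int = 50,
    min_area: int = 30,
    l_background: float = 90.0,
) -> bool:
    """Decide whether an image contains any Ki67-positive (DAB) staining.

    Thresholds the precomputed chroma projection at the precomputed
    midpoint; True iff at least min_positive_px pixels survive on the
    DAB side after small-object removal.
    """
    precomputed = precomputed or load_default_precomputed()
    image = np.asarray(image)
    lab = rgb_to_lab(image)
    nucleus = _nucleus_mask(image, lab, precomputed.cluster_model, l_background)
    proj = precomputed.transform.project(lab)
    dab_side = nucleus & (proj > precomputed.presence_threshold)
    dab_side = remove_small_objects(dab_side, max_size=min_area - 1)
    return int(dab_side.sum()) >= min_positive_px


def _postprocess(mask: np.ndarray, min_area: int) -> np.ndarray:
    mask = binary_fill_holes(mask)
    return remove_small_objects(mask, max_size=min_area - 1)


def segment_roi(
    image: np.ndarray,
    tumor_mask: np.ndarray | None = None,
    precomputed: PrecomputedModel | None = None,
    config: SegmentationConfig | None = None,
) -> SegmentationMasks:
    """Segment Ki67-positive and Ki67-negative nucleus pixels.

    Step 1 runs the precomputed-matrix presence check.  If no DAB is
    found, the positive mask is empty and negative nuclei come from the
    hematoxylin side of the precomputed projection.  Otherwise step 2
    recomputes the cluster centroids and color transform from this image
    and Kapur-thresholds the projected nucleus pixels.  Both masks get
    hole filling and small-object removal, and are intersected with the
    tumor mask when one is supplied.
    """
    cfg = config or SegmentationConfig()
    precomputed = precomputed or load_default_precomputed()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    if tumor_mask is not None and tumor_mask.shape != image.shape[:2]:
        raise ValueError(
            f"tumor mask shape {tumor_mask.shape} != image shape {image.shape[:2]}"
        )
    lab = rgb_to_lab(image)

    has_positive = detect_positive_presence(
        image, precomputed, cfg.min_positive_px, cfg.min_area, cfg.l_background
    )
    if not has_positive:
        nucleus = _nucleus_mask(image, lab, precomputed.cluster_model, cfg.l_background)
        proj = precomputed.transform.project(lab)
        neg = nucleus & (proj <= precomputed.presence_threshold)
        pos = np.zeros(image.shape[:2], dtype=bool)
        threshold = precomputed.presence_threshold
        used_precomputed = True
    else:
        model = cluster_pixels(image, k=3, seed=cfg.seed, subsample=cfg.subsample)
        transform = derive_color_transform(model)
        nucleus = _nucleus_mask(image, lab, model, cfg.l_background)
        proj = transform.project(lab)
        threshold = kapur_threshold(proj[nucleus], n_bins=cfg.n_bins)
        pos = nucleus & (proj > threshold)
        neg = nucleus & (proj <= threshold)
        used_precomputed = False

    pos = _postprocess(pos, cfg.min_area)
    neg = _postprocess(neg, cfg.min_area)
    neg &= ~pos  # hole filling may re-claim pixels; positives win
    if tumor_mask is not None:
        pos &= tumor_mask.astype(bool)
        neg &= tumor_mask.astype(bool)
    return SegmentationMasks(pos, neg, float(threshold), used_precomputed)
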