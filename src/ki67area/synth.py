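"""Synthetic Ki67-IHC ROI generator with exact per-pixel ground truth.

Renders high-power-field-like crops of Ki67-stained breast tissue:
elliptical nuclei colored with hematoxylin (Ki67-negative, blue) or
hematoxylin plus DAB (Ki67-positive, brown) on a near-white background,
using Beer-Lambert optical-density mixing with the standard H-DAB stain
vectors.  Optionally, contiguous non-tumor regions (stroma dense in
counterstained nuclei) are carved out of the tumor mask, which lets the
contamination effect of including non-tumor tissue in the index be
reproduced on demand.

Because every nucleus is placed explicitly, the generator emits exact
ground-truth masks and the exact count-based Ki67 index, so the whole
segmentation / calibration pipeline can be validated pixel-for-pixel
without any slide data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "NucleusSpec",
    "SizeDistribution",
    "StainProfile",
    "ROISpec",
    "SyntheticROI",
    "PlacementError",
    "generate_roi",
    "render_stains",
    "generate_dataset",
    "rasterize_nuclei",
    "TUMOR_LABELS",
    "NONTUMOR_LABELS",
]

TUMOR_LABELS = ("positive", "negative")
NONTUMOR_LABELS = ("nontumor_positive", "nontumor_negative")
ALL_LABELS = TUMOR_LABELS + NONTUMOR_LABELS

# Unit optical-density absorption vectors for hematoxylin and DAB
# (Ruifrok-Johnston H-DAB basis, rows normalised to unit length).
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
DAB_OD = np.array([0.269, 0.568, 0.778])


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed under the overlap policy."""


@dataclass(frozen=True)
class NucleusSpec:
    """One elliptical nucleus: geometry plus its annotation label.

    ``center_xy`` is 0-based with x = column, y = row; axes are full
    lengths in pixels; ``angle`` is the major-axis orientation in degrees.
    """

    center_xy: tuple[float, float]
    major_axis: float
    minor_axis: float
    angle: float
    label: str

    def __post_init__(self) -> None:
        if not (1.0 <= self.minor_axis <= self.major_axis):
            raise ValueError(
                f"axes must satisfy 1 <= minor <= major, got "
                f"({self.minor_axis}, {self.major_axis})"
            )
        if self.label not in ALL_LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def is_tumor(self) -> bool:
        return self.label in TUMOR_LABELS

    @property
    def is_positive(self) -> bool:
        return self.label.endswith("positive")

    def pixels(self, shape: tuple[int, int] | None = None):
        """Row/column indices of the interior, optionally clipped to shape."""
        x, y = self.center_xy
        return _draw_ellipse(
            y,
            x,
            self.minor_axis / 2.0,
            self.major_axis / 2.0,
            shape=shape,
            rotation=np.deg2rad(self.angle),
        )


@dataclass(frozen=True)
class SizeDistribution:
    """Truncated-normal distribution for nucleus axis lengths (pixels).

    Defaults emulate epithelial nuclei at a 40x-like scale: mean axis
    14 px, sd 3 px, truncated below at 6 px.
    """

    mean: float = 14.0
    sd: float = 3.0
    min_axis: float = 6.0

    def sample_axes(self, rng: np.random.Generator, scale: float = 1.0) -> tuple[float, float]:
        a = _trunc_normal(rng, self.mean, self.sd, self.min_axis) * scale
        b = _trunc_normal(rng, self.mean, self.sd, self.min_axis) * scale
        return (max(a, b), min(a, b))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    x = rng.normal(mean, sd)
    while x < low:
        x = rng.normal(mean, sd)
    return float(x)


@dataclass(frozen=True)
class StainProfile:
    """Per-label stain amounts in optical-density units.

    Negative nuclei carry hematoxylin only; positive nuclei carry DAB on
    top of a reduced hematoxylin counterstain (DAB partly masks it).
    """

    negative_hematoxylin: float = 0.90
    positive_hematoxylin: float = 0.35
    positive_dab: float = 0.90


@dataclass(frozen=True)
class ROISpec:
    """Full recipe for one synthetic ROI; the seed determines everything."""

    n_positive: int = 0
    n_negative: int = 0
    width: int = 2300
    height: int = 1200
    n_nontumor: int = 0
    nontumor_positive_frac: float = 0.0
    nontumor_region_frac: float = 0.20
    size_distribution: SizeDistribution = field(default_factory=SizeDistribution)
    positive_size_scale: float = 1.0
    negative_size_scale: float = 1.0
    stains: StainProfile = field(default_factory=StainProfile)
    overlap_policy: str = "forbid"
    noise_sd: float = 4.0
    stain_intensity_jitter: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_positive, self.n_negative, self.n_nontumor) < 0:
            raise ValueError("nucleus counts must be >= 0")
        if self.width * self.height <= 0:
            raise ValueError("image must have positive area")
        if self.overlap_policy not in ("forbid", "allow"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")
        if not 0.0 <= self.nontumor_positive_frac <= 1.0:
            raise ValueError("nontumor_positive_frac must be in [0, 1]")


@dataclass
class SyntheticROI:
    """A rendered ROI plus its exact ground truth."""

    image: np.ndarray
    nuclei: list[NucleusSpec]
    tumor_mask: np.ndarray
    gt_positive_mask: np.ndarray
    gt_negative_mask: np.ndarray
    true_index: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def render_stains(
    nuclei: Iterable[NucleusSpec],
    width: int,
    height: int,
    stains: StainProfile | None = None,
    stain_intensity_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render nuclei onto a white background via Beer-Lambert mixing.

    Per pixel, OD = sum of stain_amount * stain_vector over covering
    nuclei, and RGB = 255 * exp(-OD).  With zero jitter the interior of a
    nucleus is perfectly flat; overlapping nuclei absorb additively.
    """
    stains = stains or StainProfile()
    if stain_intensity_jitter > 0 and rng is None:
        rng = np.random.default_rng(0)
    od = np.zeros((height, width, 3), dtype=float)
    for nuc in nuclei:
        rr, cc = nuc.pixels(shape=(height, width))
        n_px = rr.size
        # Counterstain uptake and DAB deposition are independent processes,
        # and stain density also varies within a nucleus, so each stain
        # amount gets a per-nucleus and a per-pixel multiplicative draw.
        if stain_intensity_jitter > 0:
            r = stain_intensity_jitter
            fh = (1.0 + rng.uniform(-r, r)) * (1.0 + rng.uniform(-r, r, n_px))
            fd = (1.0 + rng.uniform(-r, r)) * (1.0 + rng.uniform(-r, r, n_px))
        else:
            fh = fd = np.ones(n_px)
        if nuc.is_positive:
            amounts = np.outer(stains.positive_hematoxylin * fh, HEMATOXYLIN_OD)
            amounts += np.outer(stains.positive_dab * fd, DAB_OD)
        else:
            amounts = np.outer(stains.negative_hematoxylin * fh, HEMATOXYLIN_OD)
        od[rr, cc] += amounts
    rgb = 255.0 * np.exp(-od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def _nontumor_regions(
    rng: np.random.Generator, height: int, width: int, target_frac: float
) -> np.ndarray:
    """Carve contiguous elliptical stroma blobs until ~target_frac is covered."""
    mask = np.zeros((height, width), dtype=bool)
    for _ in range(10):
        cy = rng.uniform(0.15 * height, 0.85 * height)
        cx = rng.uniform(0.15 * width, 0.85 * width)
        ry = rng.uniform(0.15, 0.30) * height
        rx = rng.uniform(0.15, 0.30) * width
        rr, cc = _draw_ellipse(cy, cx, ry, rx, shape=(height, width))
        mask[rr, cc] = True
        if mask.mean() >= target_frac:
            break
    return mask


def _place_nuclei(
    rng: np.random.Generator,
    spec: ROISpec,
    region_mask: np.ndarray,
    occupancy: np.ndarray,
    labels: Sequence[str],
    max_attempts: int = 1000,
) -> list[NucleusSpec]:
    """Place nuclei wholly inside region_mask, honoring the overlap policy."""
    height, width = region_mask.shape
    region_rows, region_cols = np.nonzero(region_mask)
    if region_rows.size == 0 and labels:
        raise PlacementError("placement region is empty")
    placed: list[NucleusSpec] = []
    for label in labels:
        scale = (spec.positive_size_scale if label.endswith("positive")
                 else spec.negative_size_scale)
        ok = False
        for _ in range(max_attempts):
            major, minor = spec.size_distribution.sample_axes(rng, scale)
            # centers drawn from region pixels: keeps the acceptance rate
            # high even when the region is a small carved-out blob
            idx = int(rng.integers(region_rows.size))
            x = region_cols[idx] + rng.uniform(-0.5, 0.5)
            y = region_rows[idx] + rng.uniform(-0.5, 0.5)
            angle = rng.uniform(0.0, 180.0)
            cand = NucleusSpec((x, y), major, minor, angle, label)
            rr, cc = cand.pixels()
            if (rr.min() < 0 or cc.min() < 0
                    or rr.max() >= height or cc.max() >= width):
                continue
            if not region_mask[rr, cc].all():
                continue
            if spec.overlap_policy == "forbid" and occupancy[rr, cc].any():
                continue
            occupancy[rr, cc] = True
            placed.append(cand)
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could only place {len(placed)} of {len(labels)} nuclei "
                f"under overlap_policy={spec.overlap_policy!r}; "
                "increase image size or reduce counts"
            )
    return placed


def generate_roi(spec: ROISpec) -> SyntheticROI:
    """Generate one ROI; deterministic for a given spec (including seed)."""
    spec.validate()
    if spec.n_positive + spec.n_negative < 1:
        raise ValueError("need at least one tumor nucleus")
    rng = np.random.default_rng(spec.seed)
    height, width = spec.height, spec.width

    if spec.n_nontumor > 0:
        nontumor = _nontumor_regions(rng, height, width, spec.nontumor_region_frac)
    else:
        nontumor = np.zeros((height, width), dtype=bool)
    tumor_mask = ~nontumor

    occupancy = np.zeros((height, width), dtype=bool)
    tumor_labels = (["positive"] * spec.n_positive
                    + ["negative"] * spec.n_negative)
    tumor_labels = list(rng.permutation(tumor_labels))
    nuclei = _place_nuclei(rng, spec, tumor_mask, occupancy, tumor_labels)

    if spec.n_nontumor > 0:
        n_pos_nt = int(round(spec.nontumor_positive_frac * spec.n_nontumor))
        nt_labels = (["nontumor_positive"] * n_pos_nt
                     + ["nontumor_negative"] * (spec.n_nontumor - n_pos_nt))
        nt_labels = list(rng.permutation(nt_labels))
        nuclei += _place_nuclei(rng, spec, nontumor, occupancy, nt_labels)

    image = render_stains(
        nuclei, width, height, spec.stains, spec.stain_intensity_jitter, rng
    )
    if spec.noise_sd > 0:
        noisy = image.astype(float) + rng.normal(0.0, spec.noise_sd, image.shape)
        image = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    gt_pos = rasterize_nuclei(nuclei, height, width, labels=("positive",))
    gt_neg = rasterize_nuclei(nuclei, height, width, labels=("negative",))
    true_index = 100.0 * spec.n_positive / (spec.n_positive + spec.n_negative)
    return SyntheticROI(image, nuclei, tumor_mask, gt_pos, gt_neg, true_index)


def rasterize_nuclei(
    nuclei: Iterable[NucleusSpec],
    height: int,
    width: int,
    labels: Sequence[str],
) -> np.ndarray:
    """Binary mask of all pixels belonging to nuclei with the given labels."""
    mask = np.zeros((height, width), dtype=bool)
    for nuc in nuclei:
        if nuc.label in labels:
            rr, cc = nuc.pixels(shape=(height, width))
            mask[rr, cc] = True
    return mask


def generate_dataset(
    n_rois: int,
    index_range: tuple[float, float] = (0.0, 80.0),
    template: ROISpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    nontumor_frac_range: tuple[float, float] | None = None,
) -> tuple[list[SyntheticROI], pd.DataFrame]:
    """Generate a dataset of ROIs with true indices ~ uniform on a range.

    ``template`` fixes the total tumor-nucleus count per ROI (its
    n_positive + n_negative); each ROI's positive count is set to hit a
    uniformly drawn target index.  When ``nontumor_frac_range`` is given,
    each ROI additionally receives a uniformly drawn fraction of
    non-tumor nuclei (relative to the tumor count) inside carved-out
    stroma regions, so the amount of contamination varies across ROIs.

    Returns the ROIs and a manifest frame.  With ``out_dir`` set, images,
    masks, an annotation CSV and the manifest CSV are also written.
    """
    lo, hi = index_range
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if not (0.0 <= lo <= hi <= 100.0):
        raise ValueError(f"invalid index range [{lo}, {hi}]")
    template = template or ROISpec(n_positive=150, n_negative=150)
    n_total = template.n_positive + template.n_negative
    if n_total < 1:
        raise ValueError("template must carry at least one tumor nucleus")

    master = np.random.default_rng(seed)
    targets = master.uniform(lo, hi, n_rois)
    roi_seeds = master.integers(0, 2**31 - 1, n_rois)
    if nontumor_frac_range is not None:
        nt_fracs = master.uniform(*nontumor_frac_range, n_rois)
    else:
        nt_fracs = None

    rois: list[SyntheticROI] = []
    rows = []
    annot_rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i in range(n_rois):
        n_pos = int(round(targets[i] * n_total / 100.0))
        n_nt = (int(round(nt_fracs[i] * n_total)) if nt_fracs is not None
                else template.n_nontumor)
        spec = replace(
            template,
            n_positive=n_pos,
            n_negative=n_total - n_pos,
            n_nontumor=n_nt,
            seed=int(roi_seeds[i]),
        )
        roi = generate_roi(spec)
        rois.append(roi)
        roi_id = f"roi_{i:03d}"
        # manifest paths are relative to the dataset directory so the
        # manifest is byte-identical wherever the dataset is written
        image_path = tumor_path = ""
        if out is not None:
            from .io import write_image, write_mask

            image_path = f"{roi_id}.png"
            tumor_path = f"{roi_id}_tumor.png"
            write_image(out / image_path, roi.image)
            write_mask(out / tumor_path, roi.tumor_mask)
            write_mask(out / f"{roi_id}_gt_pos.png", roi.gt_positive_mask)
            write_mask(out / f"{roi_id}_gt_neg.png", roi.gt_negative_mask)
            for nuc in roi.nuclei:
                annot_rows.append({
                    "roi_id": roi_id,
                    "x": round(nuc.center_xy[0], 2),
                    "y": round(nuc.center_xy[1], 2),
                    "major_axis": round(nuc.major_axis, 2),
                    "minor_axis": round(nuc.minor_axis, 2),
                    "angle": round(nuc.angle, 2),
                    "label": nuc.label,
                })
        rows.append({
            "roi_id": roi_id,
            "image_path": image_path,
            "tumor_mask_path": tumor_path,
            "true_index": roi.true_index,
            "seed": int(roi_seeds[i]),
        })
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        pd.DataFrame(
            annot_rows,
            columns=["roi_id", "x", "y", "major_axis", "minor_axis", "angle", "label"],
        ).to_csv(out / "annotations.csv", index=False)
    return rois, manifest


def load_annotations(path: str | Path) -> dict[str, list[NucleusSpec]]:
    """Read an annotation CSV back into per-ROI NucleusSpec lists."""
    df = pd.read_csv(path)
    out: dict[str, list[NucleusSpec]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.roi_id, []).append(
            NucleusSpec(
                (float(row.x), float(row.y)),
                float(row.major_axis),
                float(row.minor_axis),
                float(row.angle),
                str(row.label),
            )
        )
    return out
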