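"""Threshold-based stone segmentation and per-stone / per-kidney volumetry.

Stones are the set of voxels at or above a fixed attenuation threshold
(default 130 HU, the conventional calcification cut-off) inside each kidney
mask.  Connected components of that voxel set are individual stones; each is
measured for volume, plane-restricted maximum diameters (Feret-style, in the
x-z and y-z coordinate planes) and HU order statistics.  The per-kidney
total is the merged-VOI volume, which equals the sum of component volumes
exactly because components partition the VOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .image import LABEL_SIDES, SIDE_LABELS, KidneyMask, VolumeImage

DEFAULT_THRESHOLD_HU = 130.0
DEFAULT_MIN_DIAMETER_MM = 5.0

PLANE_AXES = {"xz": (0, 2), "yz": (1, 2)}

# Chebyshev-1 neighbor offsets grouped by face/edge/corner adjacency.
_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StoneVOI:
    """All above-threshold voxels of one kidney (the stone volume of interest)."""

    kidney_side: str
    voxels: np.ndarray            # (N, 3) integer voxel indices, possibly empty
    threshold_used: float
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.intp).reshape(-1, 3)
        if self.kidney_side not in SIDE_LABELS:
            raise ValueError(f"unknown kidney side {self.kidney_side!r}")

    @property
    def voxel_count(self) -> int:
        return self.voxels.shape[0]

    def as_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        if self.voxel_count:
            m[tuple(self.voxels.T)] = True
        return m


@dataclass
class StoneRecord:
    stone_id: int
    kidney_side: str
    voxel_count: int
    volume_ml: float
    max_diam_xz_mm: float
    max_diam_yz_mm: float
    min_hu: float
    mean_hu: float
    max_hu: float
    voxels: np.ndarray = field(repr=False, default=None)


@dataclass
class StoneInventory:
    """Per-stone records plus per-kidney totals — the quantitative reference."""

    stones: list[StoneRecord]
    spacing: tuple[float, float, float]

    def kidney_total(self, side: str) -> dict:
        records = [s for s in self.stones if s.kidney_side == side]
        return {
            "total_volume_ml": float(sum(s.volume_ml for s in records)),
            "n_stones": len(records),
        }

    @property
    def per_kidney(self) -> dict[str, dict]:
        return {side: self.kidney_total(side) for side in ("right", "left")}

    def to_frame(self):
        import pandas as pd

        cols = ["stone_id", "kidney_side", "voxel_count", "volume_ml",
                "max_diam_xz_mm", "max_diam_yz_mm", "min_hu", "mean_hu", "max_hu"]
        return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in self.stones],
                            columns=cols)


def segment_stones(image: VolumeImage, mask: KidneyMask,
                   threshold: float = DEFAULT_THRESHOLD_HU) -> dict[str, StoneVOI]:
    """Select voxels with HU >= `threshold` inside each kidney mask.

    Returns a dict with keys 'right' and 'left'; empty VOIs are allowed.
    """
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} does not match mask shape {mask.shape}")
    if not np.isfinite(image.values).all():
        raise ValueError("image contains non-finite HU values")
    above = image.values >= threshold
    out = {}
    for side in ("right", "left"):
        sel = above & mask.side(side)
        out[side] = StoneVOI(kidney_side=side,
                             voxels=np.argwhere(sel),
                             threshold_used=float(threshold),
                             grid_shape=image.shape)
    return out


def label_components(voi: StoneVOI, connectivity: int = 26) -> list[np.ndarray]:
    """Partition a VOI into maximal connected voxel sets.

    Ordering is deterministic: descending voxel count, ties broken by the
    lexicographically smallest voxel coordinate in the component.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    if voi.voxel_count == 0:
        return []
    # Label inside the bounding box only; coordinates are shifted back after.
    lo = voi.voxels.min(axis=0)
    hi = voi.voxels.max(axis=0) + 1
    box = np.zeros(tuple(hi - lo), dtype=bool)
    box[tuple((voi.voxels - lo).T)] = True
    labeled, n = ndimage.label(box, structure=_STRUCTURES[connectivity])
    comps = []
    for k in range(1, n + 1):
        vox = np.argwhere(labeled == k) + lo
        # lexicographic sort of the member voxels gives a canonical layout
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))
        comps.append(vox[order])
    comps.sort(key=lambda v: (-v.shape[0], tuple(v[0])))
    return comps


def component_volume(component: np.ndarray, spacing) -> float:
    """Volume in mL: voxel count times the physical voxel volume."""
    sx, sy, sz = (float(s) for s in spacing)
    if min(sx, sy, sz) <= 0:
        raise ValueError("spacing components must be positive")
    n = np.asarray(component).reshape(-1, 3).shape[0]
    return n * sx * sy * sz / 1000.0


def max_diameter_plane(component: np.ndarray, spacing, plane: str) -> float:
    """Maximum pairwise distance of voxel centers projected onto a plane.

    `plane` is 'xz' or 'yz'.  This is a 2D Feret-style caliper on the
    projected point cloud; a single voxel has diameter 0.
    """
    if plane not in PLANE_AXES:
        raise ValueError(f"plane must be 'xz' or 'yz', got {plane!r}")
    component = np.asarray(component).reshape(-1, 3)
    if component.shape[0] == 0:
        raise ValueError("cannot measure the diameter of an empty component")
    ax = PLANE_AXES[plane]
    sp = np.asarray(spacing, dtype=float)[list(ax)]
    pts = np.unique(component[:, ax], axis=0) * sp
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) cloud: brute force on all points
    return float(pdist(pts).max())


def hu_statistics(component: np.ndarray, image: VolumeImage) -> tuple[float, float, float]:
    """(min, mean, max) HU over the member voxels of one component."""
    component = np.asarray(component).reshape(-1, 3)
    if component.shape[0] == 0:
        raise ValueError("cannot compute HU statistics of an empty component")
    vals = image.values[tuple(component.T)]
    return float(vals.min()), float(vals.mean()), float(vals.max())


def build_inventory(image: VolumeImage, mask: KidneyMask,
                    threshold: float = DEFAULT_THRESHOLD_HU,
                    connectivity: int = 26,
                    min_diameter_mm: float | None = None) -> StoneInventory:
    """Segment, label and measure all stones of both kidneys.

    `min_diameter_mm`, if given, drops stones whose larger plane-restricted
    diameter falls below it (the clinically-insignificant small-stone
    exclusion; default threshold elsewhere is 5 mm).
    """
    vois = segment_stones(image, mask, threshold)
    stones: list[StoneRecord] = []
    sid = 0
    for side in ("right", "left"):
        for comp in label_components(vois[side], connectivity):
            mn, mean, mx = hu_statistics(comp, image)
            stones.append(StoneRecord(
                stone_id=sid,
                kidney_side=side,
                voxel_count=comp.shape[0],
                volume_ml=component_volume(comp, image.spacing),
                max_diam_xz_mm=max_diameter_plane(comp, image.spacing, "xz"),
                max_diam_yz_mm=max_diameter_plane(comp, image.spacing, "yz"),
                min_hu=mn, mean_hu=mean, max_hu=mx,
                voxels=comp,
            ))
            sid += 1
    inv = StoneInventory(stones=stones, spacing=image.spacing)
    if min_diameter_mm is not None:
        inv = filter_min_size(inv, min_diameter_mm)
    return inv


def filter_min_size(inventory: StoneInventory,
                    min_diameter_mm: float = DEFAULT_MIN_DIAMETER_MM) -> StoneInventory:
    """Drop stones whose larger plane diameter (max of xz, yz) is below the cut."""
    if min_diameter_mm < 0:
        raise ValueError("minimum diameter must be non-negative")
    kept = [s for s in inventory.stones
            if max(s.max_diam_xz_mm, s.max_diam_yz_mm) >= min_diameter_mm]
    return replace(inventory, stones=kept)
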