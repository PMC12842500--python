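"""Synthetic CT phantoms: paired kidney volumes with ellipsoidal stones.

The generator emulates a non-contrast abdominal CT acquired at 5 mm slice
spacing: two ellipsoidal "kidneys" of soft-tissue attenuation (~30 HU) on a
fat-like background (~-50 HU), containing high-attenuation ellipsoidal
stones (default 400 HU, comfortably above the 130 HU calcification
threshold), with optional additive Gaussian HU noise.

Voxel membership is by voxel center (a voxel belongs to a shape iff its
center lies inside), so digitized volumes are exact integer voxel counts
times the voxel volume and the ground truth is unambiguous.  Partial-volume
behaviour enters only through this digitization at coarse spacing, never
through HU blending.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import pi

import numpy as np

from .image import SIDE_LABELS, KidneyMask, VolumeImage
from .longitudinal import CHANGE_LABELS, classify_change

DEFAULT_SPACING = (0.7, 0.7, 5.0)
DEFAULT_STONE_HU = 400.0
DEFAULT_PARENCHYMA_HU = 30.0
DEFAULT_BACKGROUND_HU = -50.0
DEFAULT_NOISE_SD = 15.0


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid in physical mm coordinates."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)
        self.semi_axes = tuple(float(a) for a in self.semi_axes)
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        d = (np.asarray(points_mm) - self.center) / self.semi_axes
        return (d ** 2).sum(axis=-1) <= 1.0

    @property
    def volume_ml(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * pi * a * b * c / 1000.0


@dataclass
class StoneSpec:
    """One synthetic stone: a sphere or ellipsoid of fixed attenuation."""

    kidney_side: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    hu_value: float = DEFAULT_STONE_HU
    shape: str = "ellipsoid"

    def __post_init__(self) -> None:
        if self.kidney_side not in SIDE_LABELS:
            raise ValueError(f"unknown kidney side {self.kidney_side!r}")
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"shape must be 'sphere' or 'ellipsoid', got {self.shape!r}")
        self.semi_axes = tuple(float(a) for a in self.semi_axes)
        if self.shape == "sphere" and len(set(self.semi_axes)) != 1:
            raise ValueError("a sphere needs equal semi-axes")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("stone semi-axes must be positive")

    @classmethod
    def sphere(cls, kidney_side: str, center, radius: float,
               hu_value: float = DEFAULT_STONE_HU) -> "StoneSpec":
        return cls(kidney_side, tuple(center), (radius,) * 3, hu_value, shape="sphere")

    @property
    def ellipsoid(self) -> Ellipsoid:
        return Ellipsoid(self.center, self.semi_axes)

    @property
    def analytic_volume_ml(self) -> float:
        return self.ellipsoid.volume_ml

    def scaled(self, volume_factor: float) -> "StoneSpec":
        """Isotropically rescaled copy whose analytic volume is multiplied by
        `volume_factor` (> 0)."""
        if volume_factor <= 0:
            raise ValueError("volume factor must be positive")
        s = volume_factor ** (1.0 / 3.0)
        return replace(self, semi_axes=tuple(a * s for a in self.semi_axes))


@dataclass
class PhantomSpec:
    """Full description of one synthetic examination."""

    grid_shape: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    kidneys: dict[str, Ellipsoid] = field(default_factory=dict)
    stones: list[StoneSpec] = field(default_factory=list)
    parenchyma_hu: float = DEFAULT_PARENCHYMA_HU
    background_hu: float = DEFAULT_BACKGROUND_HU
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        for i, st in enumerate(self.stones):
            if st.kidney_side not in self.kidneys:
                raise ValueError(f"stone {i} assigned to kidney {st.kidney_side!r} "
                                 "which is not in the phantom")
            kid = self.kidneys[st.kidney_side]
            if not bool(kid.contains(np.asarray(st.center))):
                raise ValueError(f"stone {i} center {st.center} lies outside the "
                                 f"{st.kidney_side} kidney ellipsoid")


@dataclass
class GroundTruthStone:
    stone_id: int
    kidney_side: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    hu_value: float
    analytic_volume_ml: float
    digitized_volume_ml: float
    voxel_count: int


def _voxel_centers_mm(grid_shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    return axes


def _stone_mask(stone: StoneSpec, spec: PhantomSpec) -> np.ndarray:
    """Boolean grid of voxels whose centers are inside the stone; restricted
    to the stone's bounding box for speed."""
    ell = stone.ellipsoid
    nx, ny, nz = spec.grid_shape
    sp = spec.voxel_spacing
    # bounding box in voxel indices (voxel centers at index * spacing)
    lo = [max(0, int(np.floor((c - a) / s))) for c, a, s in zip(ell.center, ell.semi_axes, sp)]
    hi = [min(n - 1, int(np.ceil((c + a) / s)))
          for c, a, s, n in zip(ell.center, ell.semi_axes, sp, spec.grid_shape)]
    extent = [n * s for n, s in zip(spec.grid_shape, sp)]
    if any(c - a < 0 or c + a > (n - 1) * s
           for c, a, s, n in zip(ell.center, ell.semi_axes, sp, spec.grid_shape)):
        raise ValueError(
            f"stone on {stone.kidney_side} kidney at {stone.center} mm with semi-axes "
            f"{stone.semi_axes} mm extends outside the grid (extent {extent} mm)")
    mask = np.zeros(spec.grid_shape, dtype=bool)
    if any(l > h for l, h in zip(lo, hi)):
        return mask
    sub_axes = [np.arange(l, h + 1) * s for l, h, s in zip(lo, hi, sp)]
    X, Y, Z = np.meshgrid(*sub_axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = ell.contains(pts)
    return mask


def generate_phantom(spec: PhantomSpec):
    """Render a phantom into (VolumeImage, KidneyMask, ground truth list).

    Deterministic for a fixed ``spec.seed``.  Raises if a stone extends
    outside the grid or if two stones in the same kidney overlap (the
    ground truth must stay unambiguous).
    """
    sp = spec.voxel_spacing
    hu = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)

    axes = _voxel_centers_mm(spec.grid_shape, sp)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    for side, ell in spec.kidneys.items():
        inside = ell.contains(pts)
        hu[inside] = spec.parenchyma_hu
        labels[inside] = SIDE_LABELS[side]

    voxel_ml = sp[0] * sp[1] * sp[2] / 1000.0
    claimed = {side: np.zeros(spec.grid_shape, dtype=bool) for side in spec.kidneys}
    truth: list[GroundTruthStone] = []
    for i, stone in enumerate(spec.stones):
        m = _stone_mask(stone, spec)
        if (m & claimed[stone.kidney_side]).any():
            raise ValueError(f"stone {i} overlaps an earlier stone in the "
                             f"{stone.kidney_side} kidney")
        claimed[stone.kidney_side] |= m
        hu[m] = stone.hu_value
        truth.append(GroundTruthStone(
            stone_id=i,
            kidney_side=stone.kidney_side,
            center=stone.center,
            semi_axes=stone.semi_axes,
            hu_value=stone.hu_value,
            analytic_volume_ml=stone.analytic_volume_ml,
            digitized_volume_ml=int(m.sum()) * voxel_ml,
            voxel_count=int(m.sum()),
        ))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    return VolumeImage(hu, sp), KidneyMask(labels), truth


@dataclass
class ChangeScenario:
    """Baseline phantom plus per-stone fractional volume changes.

    Follow-up volume of stone *i* is ``baseline * (1 + f_i)``; ``f = -1``
    removes the stone.  ``expected_label`` maps each kidney to the label the
    15% band rule implies for the *analytic* per-kidney totals.
    """

    baseline: PhantomSpec
    volume_change_fraction: list[float]
    band: float = 0.15
    followup_seed_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.volume_change_fraction) != len(self.baseline.stones):
            raise ValueError("need one change fraction per baseline stone")
        for f in self.volume_change_fraction:
            if 1.0 + f < 0:
                raise ValueError(f"volume change fraction {f} implies negative volume")

    def followup_spec(self) -> PhantomSpec:
        stones = []
        for stone, f in zip(self.baseline.stones, self.volume_change_fraction):
            if 1.0 + f == 0.0:
                continue  # stone resolved
            stones.append(stone.scaled(1.0 + f))
        return replace(self.baseline, stones=stones,
                       seed=self.baseline.seed + self.followup_seed_offset)

    def expected_labels(self) -> dict[str, str]:
        """Per-kidney labels from the band rule on analytic total volumes."""
        out = {}
        fu = self.followup_spec()
        for side in self.baseline.kidneys:
            vb = sum(s.analytic_volume_ml for s in self.baseline.stones
                     if s.kidney_side == side)
            vf = sum(s.analytic_volume_ml for s in fu.stones
                     if s.kidney_side == side)
            out[side] = classify_change(vb, vf, band=self.band)
        return out


def generate_followup(scenario: ChangeScenario):
    """Render the follow-up examination of a change scenario."""
    return generate_phantom(scenario.followup_spec())


@dataclass
class ReaderSimSpec:
    """Categorical reader emulator: a row-stochastic confusion matrix over
    (decreased, stable, increased) giving P(reported | true)."""

    confusion: np.ndarray
    seed: int = 0
    categories: tuple[str, ...] = CHANGE_LABELS

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=float)
        k = len(self.categories)
        if self.confusion.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if (self.confusion < 0).any() or (self.confusion > 1).any():
            raise ValueError("confusion entries must lie in [0, 1]")
        if not np.allclose(self.confusion.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("confusion rows must each sum to 1")


def simulate_readers(true_labels: list[str], spec: ReaderSimSpec) -> list[str]:
    """Sample one reported label per true label from its confusion row."""
    idx = {c: i for i, c in enumerate(spec.categories)}
    unknown = set(true_labels) - set(spec.categories)
    if unknown:
        raise ValueError(f"unknown change categories: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    cats = np.asarray(spec.categories, dtype=object)
    rows = np.array([idx[lab] for lab in true_labels], dtype=np.intp)
    # inverse-CDF sampling, one uniform draw per label
    cdf = np.cumsum(spec.confusion, axis=1)
    u = rng.random(len(rows))
    picks = (u[:, None] > cdf[rows]).sum(axis=1)
    return list(cats[picks])
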