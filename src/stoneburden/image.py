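"""Core in-memory containers for CT-like volumes and kidney masks.

Conventions
-----------
Arrays are indexed ``(x, y, z)``; ``spacing`` is the physical voxel size in
mm in the same order.  Voxel *centers* sit at ``index * spacing`` (0-based),
so physical coordinates of voxel ``(i, j, k)`` are
``(i*sx, j*sy, k*sz)`` mm.  Volumes are reported in mL
(1 mL = 1000 mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RIGHT = 1
LEFT = 2
SIDE_LABELS = {"right": RIGHT, "left": LEFT}
LABEL_SIDES = {RIGHT: "right", LEFT: "left"}


@dataclass
class VolumeImage:
    """A 3D scalar grid of Hounsfield units with physical voxel spacing."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("image must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class KidneyMask:
    """Label grid over the same shape as the image.

    0 = background, 1 = right kidney, 2 = left kidney.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("mask must be a non-empty 3D grid")
        bad = np.setdiff1d(np.unique(self.labels), [0, RIGHT, LEFT])
        if bad.size:
            raise ValueError(f"mask contains invalid labels {bad.tolist()}; allowed are 0, 1, 2")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def side(self, side: str) -> np.ndarray:
        """Boolean array selecting one kidney ('left' or 'right')."""
        if side not in SIDE_LABELS:
            raise ValueError(f"unknown kidney side {side!r}")
        return self.labels == SIDE_LABELS[side]


@dataclass
class KidneyStudy:
    """Paired baseline/follow-up examination of one patient."""

    patient_id: str
    baseline: VolumeImage
    followup: VolumeImage
    mask_baseline: KidneyMask
    mask_followup: KidneyMask
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline.shape != self.mask_baseline.shape:
            raise ValueError("baseline image and mask shapes differ")
        if self.followup.shape != self.mask_followup.shape:
            raise ValueError("follow-up image and mask shapes differ")
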