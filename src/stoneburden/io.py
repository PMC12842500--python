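"""NIfTI, CSV and YAML config I/O.

Images and masks travel as NIfTI (.nii / .nii.gz) with an RAS affine whose
diagonal encodes the voxel spacing in mm.  Tables are plain CSV; volumes are
written in mL to 5 decimals and lengths in mm to 2, which is part of the
public contract.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .image import KidneyMask, VolumeImage

ML_DECIMALS = 5
MM_DECIMALS = 2


def write_volume(image: VolumeImage, path) -> None:
    affine = np.diag(list(image.spacing) + [1.0])
    affine[:3, 3] = image.origin
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), affine), str(path))


def read_volume(path) -> VolumeImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # corrupt or non-NIfTI input
        raise ValueError(f"cannot read NIfTI image {path}: {exc}") from exc
    spacing = tuple(float(z) for z in zooms)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeImage(data, spacing, origin)


def write_mask(mask: KidneyMask, spacing, path, origin=(0.0, 0.0, 0.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8), affine), str(path))


def read_mask(path) -> KidneyMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI mask {path}: {exc}") from exc
    if not np.all(np.isin(np.unique(data), [0, 1, 2])):
        raise ValueError(f"mask {path} contains labels other than 0 (background), "
                         "1 (right kidney), 2 (left kidney)")
    return KidneyMask(data.astype(np.uint8))


def write_ground_truth_csv(truth, path) -> None:
    """One row per synthetic stone: geometry, HU and both volume accounts."""
    rows = []
    for s in truth:
        rows.append({
            "stone_id": s.stone_id,
            "kidney_side": s.kidney_side,
            "center_x_mm": round(s.center[0], MM_DECIMALS),
            "center_y_mm": round(s.center[1], MM_DECIMALS),
            "center_z_mm": round(s.center[2], MM_DECIMALS),
            "semi_axis_x_mm": round(s.semi_axes[0], MM_DECIMALS),
            "semi_axis_y_mm": round(s.semi_axes[1], MM_DECIMALS),
            "semi_axis_z_mm": round(s.semi_axes[2], MM_DECIMALS),
            "hu": s.hu_value,
            "analytic_volume_ml": round(s.analytic_volume_ml, ML_DECIMALS),
            "digitized_volume_ml": round(s.digitized_volume_ml, ML_DECIMALS),
            "voxel_count": s.voxel_count,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def inventory_frame(inventory, patient_id: str = "", timepoint: str = "") -> pd.DataFrame:
    df = inventory.to_frame()
    if not df.empty:
        df["volume_ml"] = df["volume_ml"].round(ML_DECIMALS)
        for c in ("max_diam_xz_mm", "max_diam_yz_mm"):
            df[c] = df[c].round(MM_DECIMALS)
    if patient_id:
        df.insert(0, "patient_id", patient_id)
    if timepoint:
        df.insert(1, "timepoint", timepoint)
    return df


@dataclass
class PipelineConfig:
    """Everything the end-to-end comparison needs; mirrors the YAML config."""

    input_dir: str = ""
    output_dir: str = ""
    threshold_hu: float = 130.0
    band: float = 0.15
    min_diameter_mm: float = 5.0
    connectivity: int = 26
    bin_width: float = 25.0
    wavelet_on: bool = True
    seed: int = 0
    kappa_bootstrap: int = 2000
    extract_radiomics: bool = True

    def __post_init__(self) -> None:
        if self.threshold_hu <= 0 or self.min_diameter_mm < 0 or self.bin_width <= 0:
            raise ValueError("threshold, minimum diameter and bin width must be positive")
        if not 0 < self.band < 1:
            raise ValueError(f"band must lie in (0, 1), got {self.band}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
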