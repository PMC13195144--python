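"""Labeled voxel point clouds and their file formats.

A subject is a flat list of voxels: world-space position (mm), SUV value
and fine organ label. Tabular round-trip formats are CSV and Parquet with
columns ``x, y, z, suv, label``; NIfTI volume + integer multi-label mask
pairs are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["LabeledPointCloud", "read_point_cloud", "write_point_cloud", "read_nifti_subject"]

_COLUMNS = ("x", "y", "z", "suv", "label")


@dataclass
class LabeledPointCloud:
    """One subject's voxels: N×3 positions (mm), N SUVs, N organ labels."""

    positions: np.ndarray
    suv: np.ndarray
    labels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.suv = np.asarray(self.suv, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.suv)
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be ({n}, 3), got {self.positions.shape}")
        if self.labels.shape != (n,):
            raise ValueError("labels length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not np.all(np.isfinite(self.suv)):
            raise ValueError("SUV values must be finite")
        if np.any(self.suv < 0):
            raise ValueError("SUV values must be >= 0")

    def __len__(self) -> int:
        return len(self.suv)

    def organs(self) -> list[str]:
        """Distinct labels in first-appearance-stable sorted order."""
        return sorted(set(self.labels.tolist()))

    def select(self, label: str) -> "LabeledPointCloud":
        """Single-organ sub-cloud for `label` (voxel order preserved)."""
        mask = self.labels == label
        if not mask.any():
            raise KeyError(f"no voxels labeled {label!r} in subject {self.subject_id!r}")
        return LabeledPointCloud(
            self.positions[mask], self.suv[mask], self.labels[mask], self.subject_id
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "suv": self.suv,
                "label": self.labels.astype(str),
            }
        )


def write_point_cloud(cloud: LabeledPointCloud, path: str | Path) -> None:
    """Write as CSV or Parquet depending on the file suffix."""
    path = Path(path)
    frame = cloud.to_frame()
    if path.suffix == ".parquet":
        frame.to_parquet(path, index=False)
    else:
        frame.to_csv(path, index=False)


def read_point_cloud(path: str | Path, subject_id: str | None = None) -> LabeledPointCloud:
    path = Path(path)
    if path.suffix == ".parquet":
        frame = pd.read_parquet(path)
    else:
        frame = pd.read_csv(path)
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return LabeledPointCloud(
        frame[["x", "y", "z"]].to_numpy(dtype=float),
        frame["suv"].to_numpy(dtype=float),
        frame["label"].to_numpy(dtype=object),
        subject_id if subject_id is not None else path.stem,
    )


def read_nifti_subject(
    pet_path: str | Path,
    mask_path: str | Path,
    label_map: Mapping[int, str],
    subject_id: str = "",
) -> LabeledPointCloud:
    """Convert a PET volume + integer multi-label mask into a point cloud.

    Voxels with nonzero mask value become points at world-space mm
    coordinates (via the shared affine); SUV comes from the PET volume and
    labels from ``label_map`` (mask integer → organ name).
    """
    import nibabel as nib

    pet_img = nib.load(str(pet_path))
    mask_img = nib.load(str(mask_path))
    if pet_img.shape != mask_img.shape:
        raise ValueError(f"shape mismatch: PET {pet_img.shape} vs mask {mask_img.shape}")
    if not np.allclose(pet_img.affine, mask_img.affine, atol=1e-6):
        raise ValueError("PET and mask affines differ")
    pet = np.asarray(pet_img.dataobj, dtype=float)
    mask = np.asarray(mask_img.dataobj).astype(int)

    idx = np.argwhere(mask != 0)
    ids = mask[mask != 0]
    unknown = sorted(set(ids.tolist()) - set(int(k) for k in label_map))
    if unknown:
        raise KeyError(f"mask label ids without a name: {unknown}")
    world = nib.affines.apply_affine(pet_img.affine, idx)
    labels = np.array([label_map[int(i)] for i in ids], dtype=object)
    return LabeledPointCloud(world, pet[tuple(idx.T)], labels, subject_id)
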