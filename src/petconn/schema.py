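"""13-ROI meta-organ schema and the fine-organ → ROI mapping.

The fine label vocabulary follows TotalSegmentator-style snake_case names;
the 13 regions of interest group anatomically or functionally related
organs. The canonical ROI order defined here is used for every matrix the
package produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["ROISchema", "ROI_NAMES", "ORGAN_TO_ROI", "default_schema"]

ROI_NAMES: tuple[str, ...] = (
    "Axial Skeleton",
    "Appendicular Skeleton",
    "Skeletal Muscles",
    "Lung",
    "VAT Fat",
    "SAT Fat",
    "Liver",
    "Spleen",
    "Kidney",
    "Heart Left",
    "Heart Right",
    "Brain",
    "Pancreas",
)

ORGAN_TO_ROI: dict[str, str] = {
    # Axial Skeleton
    "costal_cartilages": "Axial Skeleton",
    "ribs": "Axial Skeleton",
    "sacrum": "Axial Skeleton",
    "skull": "Axial Skeleton",
    "sternum": "Axial Skeleton",
    "vertebrae_c": "Axial Skeleton",
    "vertebrae_ls": "Axial Skeleton",
    "vertebrae_t": "Axial Skeleton",
    # Appendicular Skeleton
    "femur_left": "Appendicular Skeleton",
    "femur_right": "Appendicular Skeleton",
    "hip_left": "Appendicular Skeleton",
    "hip_right": "Appendicular Skeleton",
    "humerus_left": "Appendicular Skeleton",
    "humerus_right": "Appendicular Skeleton",
    "shoulder_girdle": "Appendicular Skeleton",
    # Skeletal Muscles
    "autochthon_left": "Skeletal Muscles",
    "autochthon_right": "Skeletal Muscles",
    "gluteus_left": "Skeletal Muscles",
    "gluteus_right": "Skeletal Muscles",
    "iliopsoas_left": "Skeletal Muscles",
    "iliopsoas_right": "Skeletal Muscles",
    "skeletal_muscle": "Skeletal Muscles",
    # Lung
    "lung_lower_lobe_left": "Lung",
    "lung_lower_lobe_right": "Lung",
    "lung_middle_lobe_right": "Lung",
    "lung_upper_lobe_left": "Lung",
    "lung_upper_lobe_right": "Lung",
    # Fat depots
    "torso_fat": "VAT Fat",
    "subcutaneous_fat": "SAT Fat",
    # Single-organ ROIs
    "liver": "Liver",
    "spleen": "Spleen",
    "brain": "Brain",
    "pancreas": "Pancreas",
    # Kidney
    "kidney_left": "Kidney",
    "kidney_right": "Kidney",
    # Heart
    "heart_atrium_left": "Heart Left",
    "heart_ventricle_left": "Heart Left",
    "heart_myocardium": "Heart Left",
    "heart_atrium_right": "Heart Right",
    "heart_ventricle_right": "Heart Right",
}


@dataclass(frozen=True)
class ROISchema:
    """Ordered ROI names plus a total map from fine organ labels to ROIs.

    Parameters
    ----------
    roi_names:
        Ordered meta-organ names; defines canonical matrix row order.
    organ_to_roi:
        Mapping from every fine organ label in use to its ROI. Each fine
        label maps to exactly one ROI and every target ROI must appear in
        ``roi_names``.
    """

    roi_names: tuple[str, ...] = ROI_NAMES
    organ_to_roi: Mapping[str, str] = field(default_factory=lambda: dict(ORGAN_TO_ROI))

    def __post_init__(self) -> None:
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("duplicate ROI names")
        unknown = {r for r in self.organ_to_roi.values()} - set(self.roi_names)
        if unknown:
            raise ValueError(f"organ_to_roi targets not in roi_names: {sorted(unknown)}")

    def roi_of(self, organ: str) -> str:
        try:
            return self.organ_to_roi[organ]
        except KeyError:
            raise KeyError(f"organ label {organ!r} is not mapped to any ROI") from None

    def organs_of(self, roi: str) -> list[str]:
        return sorted(o for o, r in self.organ_to_roi.items() if r == roi)

    def roi_index(self, roi: str) -> int:
        return self.roi_names.index(roi)

    def validate_labels(self, labels: Iterable[str]) -> None:
        """Raise if any label in `labels` is missing from the mapping."""
        missing = sorted(set(labels) - set(self.organ_to_roi))
        if missing:
            raise KeyError(f"labels without ROI mapping: {missing}")


def default_schema() -> ROISchema:
    """Schema with the canonical 13 ROIs and the full fine-organ table."""
    return ROISchema()
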