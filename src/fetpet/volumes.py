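"""Core image containers and NIfTI / JSON input-output.

The pipeline works on static 3D PET volumes. Two in-memory containers cover
every stage: :class:`ImageVolume` for scalar grids (activity concentration in
kBq/ml, or dimensionless SUV) and :class:`Mask` for binary structures (tumor
ROI, background reference region, MRI-based target volume, isocontour).
Injection metadata needed for SUV conversion travels as
:class:`InjectionRecord`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np

UNIT_ACTIVITY = "activity_kBq_per_ml"
UNIT_SUV = "suv"

MASK_ROLES = ("roi", "reference", "mri_target", "isocontour")

#: F-18 physical half-life in minutes.
F18_HALF_LIFE_MIN = 109.77


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing and a physical unit.

    Parameters
    ----------
    values
        3D float array.
    voxel_spacing_mm
        Per-axis voxel edge length in millimetres; all entries positive.
    unit
        ``"activity_kBq_per_ml"`` or ``"suv"``.
    affine
        Optional 4x4 voxel-to-world matrix; defaults to a diagonal scaling
        by the voxel spacing (needed only for cross-grid resampling).
    """

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    unit: str
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be three positive reals")
        if self.unit not in (UNIT_ACTIVITY, UNIT_SUV):
            raise ValueError(f"unknown unit {self.unit!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (1 mm^3 = 1e-3 ml)."""
        return float(np.prod(self.voxel_spacing_mm)) / 1000.0

    def world_affine(self) -> np.ndarray:
        return self.affine if self.affine is not None else _default_affine(self.voxel_spacing_mm)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "ImageVolume":
        return replace(self, values=values, unit=unit or self.unit)


@dataclass
class Mask:
    """A binary 3D structure on a stated voxel grid."""

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    role: str = "roi"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask values must be a 3D array")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be three positive reals")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_spacing_mm)) / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def world_affine(self) -> np.ndarray:
        return self.affine if self.affine is not None else _default_affine(self.voxel_spacing_mm)


def same_grid(a: ImageVolume | Mask, b: ImageVolume | Mask) -> bool:
    return a.shape == b.shape and np.allclose(a.voxel_spacing_mm, b.voxel_spacing_mm)


def require_same_grid(a: ImageVolume | Mask, b: ImageVolume | Mask, what: str = "inputs") -> None:
    if not same_grid(a, b):
        raise ValueError(
            f"{what} must share one grid: shapes {a.shape} vs {b.shape}, "
            f"spacings {a.voxel_spacing_mm} vs {b.voxel_spacing_mm}"
        )


@dataclass
class InjectionRecord:
    """Tracer administration metadata needed to convert activity to SUV.

    ``decay_corrected`` states whether the activity volume is already
    decay-corrected to injection time (the usual DICOM convention). When it
    is not, SUV conversion applies an explicit F-18 decay correction over
    the injection-to-acquisition interval.
    """

    injected_activity_MBq: float
    body_weight_kg: float
    injection_time: datetime
    acquisition_time: datetime
    decay_corrected: bool = True
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if isinstance(self.injection_time, str):
            self.injection_time = datetime.fromisoformat(self.injection_time)
        if isinstance(self.acquisition_time, str):
            self.acquisition_time = datetime.fromisoformat(self.acquisition_time)
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected_activity_MBq must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be positive")
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be positive")
        if self.acquisition_time < self.injection_time:
            raise ValueError("acquisition_time must not precede injection_time")

    @property
    def uptake_minutes(self) -> float:
        return (self.acquisition_time - self.injection_time).total_seconds() / 60.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "injected_activity_MBq": self.injected_activity_MBq,
            "body_weight_kg": self.body_weight_kg,
            "injection_time": self.injection_time.isoformat(),
            "acquisition_time": self.acquisition_time.isoformat(),
            "decay_corrected": self.decay_corrected,
            "half_life_min": self.half_life_min,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "InjectionRecord":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# NIfTI round-trip


def save_volume(vol: ImageVolume | Mask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1 (masks as uint8)."""
    data = vol.values.astype(np.uint8) if isinstance(vol, Mask) else vol.values
    img = nib.Nifti1Image(data, vol.world_affine())
    img.header.set_zooms(vol.voxel_spacing_mm)
    nib.save(img, str(path))


def load_image(path: str | Path, unit: str = UNIT_ACTIVITY) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asanyarray(img.dataobj), spacing, unit, affine=np.asarray(img.affine))


def load_mask(path: str | Path, role: str = "roi") -> Mask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Mask(np.asanyarray(img.dataobj) > 0.5, spacing, role, affine=np.asarray(img.affine))
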