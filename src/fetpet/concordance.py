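"""Agreement between PET isocontour volumes and MRI-based target volumes.

The conformity index (CI) is the Jaccard overlap: intersection volume of the
PET volume (PETvol) and the MRI-based treatment volume (MRIvol) divided by
their union. The Dice coefficient relates to it by D = 2J/(1+J). The
"best matching isocontour" is the %SUVmax level whose isocontour maximizes
CI with MRIvol; the added-volume metrics quantify how much treating the
union of PETvol and MRIvol would enlarge the treated volume relative to
MRIvol alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .isocontour import IsocontourSet
from .volumes import ImageVolume, Mask, same_grid


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-level overlap summary between one isocontour and MRIvol."""

    level_pct: float
    petvol_ml: float
    mrivol_ml: float
    intersection_ml: float
    union_ml: float
    ci: float
    dice: float
    added_volume_ml: float
    pct_increase: float


@dataclass
class ConcordanceTable:
    """All per-level records for one patient plus the best matching isocontour.

    ``best_level_pct`` is the smallest level attaining the maximal CI
    (tie-break toward the larger, more conservative volume).
    """

    patient: str
    records: list[ConcordanceRecord]
    best_level_pct: float
    best_ci: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = r.__dict__.copy()
            d["patient"] = self.patient
            d["is_best"] = r.level_pct == self.best_level_pct
            rows.append(d)
        cols = [
            "patient", "level_pct", "petvol_ml", "mrivol_ml", "intersection_ml",
            "union_ml", "ci", "dice", "added_volume_ml", "pct_increase", "is_best",
        ]
        return pd.DataFrame(rows)[cols]


def resample_to_grid(mask: Mask, target: ImageVolume | Mask) -> Mask:
    """Nearest-neighbour resampling of an already-aligned mask onto a target grid.

    Both inputs must carry voxel-to-world affines placing them in one world
    frame (rigid registration itself is out of scope). When source and
    target grids already match, the mask is returned unchanged up to a copy.
    """
    src_aff = mask.world_affine()
    tgt_aff = target.world_affine()
    if mask.shape == target.shape and np.allclose(src_aff, tgt_aff):
        return Mask(mask.values.copy(), target.voxel_spacing_mm, mask.role,
                    affine=target.affine)
    # target voxel index -> world -> source voxel index, then order-0 lookup
    src_from_tgt = np.linalg.inv(src_aff) @ tgt_aff
    idx = np.indices(target.shape, dtype=float).reshape(3, -1)
    coords = src_from_tgt[:3, :3] @ idx + src_from_tgt[:3, 3:4]
    values = ndimage.map_coordinates(
        mask.values.astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).reshape(target.shape)
    return Mask(values > 0, target.voxel_spacing_mm, mask.role, affine=target.affine)


def conformity(pet_mask: Mask, mri_mask: Mask) -> ConcordanceRecord:
    """Conformity index, Dice, and added-volume metrics for one mask pair.

    An empty PET mask is a valid degenerate input (CI = 0); an empty MRI
    target volume is not, because pct_increase is referenced to it.
    """
    if not same_grid(pet_mask, mri_mask):
        raise ValueError("PET and MRI masks must share one grid")
    if mri_mask.is_empty():
        raise ValueError("MRI target mask is empty")
    vox_ml = pet_mask.voxel_volume_ml
    pet_n = pet_mask.voxel_count
    mri_n = mri_mask.voxel_count
    inter_n = int(np.count_nonzero(pet_mask.values & mri_mask.values))
    union_n = pet_n + mri_n - inter_n
    ci = inter_n / union_n
    dice = 2.0 * inter_n / (pet_n + mri_n)
    added_n = union_n - mri_n
    return ConcordanceRecord(
        level_pct=float("nan"),
        petvol_ml=pet_n * vox_ml,
        mrivol_ml=mri_n * vox_ml,
        intersection_ml=inter_n * vox_ml,
        union_ml=union_n * vox_ml,
        ci=ci,
        dice=dice,
        added_volume_ml=added_n * vox_ml,
        pct_increase=100.0 * added_n / mri_n,
    )


def best_matching_isocontour(iso: IsocontourSet, mri_mask: Mask, patient: str = "patient") -> ConcordanceTable:
    """Score every isocontour level against MRIvol and flag the best CI.

    Ties in CI are broken toward the smallest level (the largest isocontour
    volume), the conservative choice for target coverage.
    """
    if not iso.levels_pct:
        raise ValueError("isocontour set has no levels")
    records = []
    for level in iso.levels_pct:
        rec = conformity(iso.masks[level], mri_mask)
        records.append(ConcordanceRecord(**{**rec.__dict__, "level_pct": level}))
    best = max(records, key=lambda r: (r.ci, -r.level_pct))
    return ConcordanceTable(patient, records, best.level_pct, best.ci)
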