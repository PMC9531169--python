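"""%SUVmax isocontour masks within the tumor ROI and their volumes.

An isocontour at level x keeps every ROI voxel whose SUV is at least
x% of the ROI's SUVmax (threshold inclusive, so level 100 keeps the argmax
voxel(s)). No connected-component pruning is applied: satellite
supra-threshold voxels inside the ROI are retained. Volumes are reported in
ml (identical to cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass

from .suvquant import suvmax_in_roi
from .volumes import ImageVolume, Mask

DEFAULT_LEVELS = (40, 50, 60, 70)


def volume_ml(mask: Mask) -> float:
    """Voxel count times voxel volume, in ml; an empty mask has volume 0."""
    return mask.voxel_count * mask.voxel_volume_ml


@dataclass
class IsocontourSet:
    """Isocontour masks per %SUVmax level, with volumes and the SUVmax used.

    For levels a < b the level-b mask is a subset of the level-a mask, so
    volumes are non-increasing in level.
    """

    levels_pct: tuple[float, ...]
    masks: dict[float, Mask]
    volumes_ml: dict[float, float]
    suvmax_used: float


def isocontours(suv: ImageVolume, roi: Mask, levels_pct=DEFAULT_LEVELS) -> IsocontourSet:
    """Build the %SUVmax isocontours inside the ROI.

    mask(level) = { v in ROI : SUV(v) >= level/100 * SUVmax(ROI) }.
    Thresholds are relative to SUVmax, so rescaling the SUV volume by any
    positive constant leaves every mask unchanged.
    """
    levels = tuple(float(l) for l in levels_pct)
    if not levels:
        raise ValueError("levels_pct must be non-empty")
    if any(l <= 0 or l > 100 for l in levels):
        raise ValueError("each level must lie in (0, 100]")
    smax = suvmax_in_roi(suv, roi)  # validates grid and non-empty ROI
    masks: dict[float, Mask] = {}
    volumes: dict[float, float] = {}
    for level in sorted(levels):
        sel = roi.values & (suv.values >= level / 100.0 * smax)
        m = Mask(sel, suv.voxel_spacing_mm, role="isocontour", affine=suv.affine)
        masks[level] = m
        volumes[level] = volume_ml(m)
    return IsocontourSet(tuple(sorted(levels)), masks, volumes, smax)
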