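"""SUV conversion and ROI-restricted uptake metrics (SUVmax, SURmax).

The standardized uptake value normalizes tissue activity concentration by
injected dose per body weight (body-weight SUV with the 1 g/ml tissue
density convention, so SUV is dimensionless):

    SUV(v) = C(v) [kBq/ml] / (injected activity [kBq] / body weight [g])

SURmax divides the ROI's SUVmax by the mean SUV of a background reference
region drawn in unaffected brain, giving a background-corrected uptake
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import UNIT_ACTIVITY, UNIT_SUV, ImageVolume, Mask, require_same_grid


@dataclass(frozen=True)
class UptakeMetrics:
    """SUVmax of the tumor ROI, mean SUV of the reference region, and their quotient."""

    suvmax: float
    ref_mean_suv: float
    surmax: float


def to_suv(activity: ImageVolume, injection) -> ImageVolume:
    """Convert an activity-concentration volume (kBq/ml) to SUV, voxel-wise.

    Dose per body weight is ``injected_activity / body_weight`` in kBq/g;
    with tissue density 1 g/ml this makes SUV dimensionless. If the input
    is not decay-corrected to injection time, activity is first multiplied
    by ``exp(ln2 * dt / half_life)`` with ``dt`` the injection-to-
    acquisition interval in minutes.
    """
    if activity.unit != UNIT_ACTIVITY:
        raise ValueError(f"expected an activity volume, got unit {activity.unit!r}")
    # kBq/g: (MBq * 1000 kBq/MBq) / (kg * 1000 g/kg)
    dose_per_weight = injection.injected_activity_MBq / injection.body_weight_kg
    values = activity.values
    if not injection.decay_corrected:
        values = values * np.exp(np.log(2.0) * injection.uptake_minutes / injection.half_life_min)
    return activity.with_values(values / dose_per_weight, unit=UNIT_SUV)


def suvmax_in_roi(suv: ImageVolume, roi: Mask) -> float:
    """Maximum SUV over ROI voxels; everything outside the ROI is ignored.

    High-uptake structures that are not tumor (vessels, basal ganglia) are
    handled by excluding them from the ROI, so they never drive SUVmax.
    """
    require_same_grid(suv, roi, "SUV volume and ROI")
    if roi.is_empty():
        raise ValueError("ROI is empty")
    return float(suv.values[roi.values].max())


def surmax(suv: ImageVolume, roi: Mask, reference: Mask) -> UptakeMetrics:
    """SUVmax / mean reference SUV, with the intermediate quantities.

    The reference mask must be disjoint from the ROI (it represents
    unaffected background, typically contralateral brain).
    """
    require_same_grid(suv, roi, "SUV volume and ROI")
    require_same_grid(suv, reference, "SUV volume and reference region")
    if roi.is_empty():
        raise ValueError("ROI is empty")
    if reference.is_empty():
        raise ValueError("reference region is empty")
    if np.any(roi.values & reference.values):
        raise ValueError("reference region overlaps the tumor ROI")
    ref_mean = float(suv.values[reference.values].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference region mean SUV must be positive, got {ref_mean}")
    smax = suvmax_in_roi(suv, roi)
    return UptakeMetrics(suvmax=smax, ref_mean_suv=ref_mean, surmax=smax / ref_mean)
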