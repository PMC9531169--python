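"""Build a PET phantom, convert it to SUV, and extract %SUVmax isocontours.

A single Gaussian uptake hotspot (peak 10 kBq/ml over a 1 kBq/ml tissue
background) is generated on a 32^3 grid of 2 mm voxels, converted to SUV
with a typical injection record (180 MBq, 72 kg), and segmented at the
40/50/60/70 %SUVmax levels within a whole-grid ROI.
"""

from datetime import datetime

import numpy as np

from fetpet import (
    InjectionRecord,
    Mask,
    PhantomSpec,
    isocontours,
    make_pet_phantom,
    suvmax_in_roi,
    to_suv,
)

spec = PhantomSpec(
    grid_shape=(32, 32, 32),
    voxel_spacing_mm=(2.0, 2.0, 2.0),
    background_uptake=1.0,
    hotspots=[((16, 16, 16), (7.0, 7.0, 7.0), 10.0)],
    noise_sd=0.3,
    seed=7,
)
injection = InjectionRecord(
    injected_activity_MBq=180.0,
    body_weight_kg=72.0,
    injection_time=datetime(2022, 3, 1, 9, 30),
    acquisition_time=datetime(2022, 3, 1, 9, 42),
)

pet, truth = make_pet_phantom(spec, injection)
suv = to_suv(pet, injection)
roi = Mask(np.ones(pet.shape, bool), pet.voxel_spacing_mm, "roi")

print(f"true (noise-free) SUVmax: {truth.true_suvmax:.3f}")
print(f"measured SUVmax in ROI:   {suvmax_in_roi(suv, roi):.3f}")
print()
print("level   volume [ml]   (noise-free truth)")
iso = isocontours(suv, roi)
for level in iso.levels_pct:
    print(f"  {level:3.0f}%   {iso.volumes_ml[level]:8.3f}     "
          f"({truth.true_isocontour_volumes_ml[level]:.3f})")
print()
print("Volumes shrink as the threshold rises (nested isocontours); the")
print("measured SUVmax sits slightly above the noise-free truth because the")
print("maximum statistic rides on top of the added voxel noise.")
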