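"""Synthetic inputs with known ground truth for every pipeline stage.

The study's patient data (PET volumes, planning MRI contours, clinical
follow-up, blood microarrays) are not publicly deposited, so this module
generates stand-ins whose true answers are known by construction:

* PET phantoms: tissue background plus anisotropic Gaussian uptake
  hotspots plus i.i.d. Gaussian noise, clipped at zero (no scanner PSF or
  reconstruction modelling — the goal is stressing max- and
  threshold-statistics, not PET physics);
* MRI-like target-volume masks built to hit a requested conformity index
  against a chosen %SUVmax isocontour;
* right-censored survival cohorts whose event times follow the same
  log-logistic AFT law the analysis fits, with the effect switching at a
  true SUVmax cutoff;
* expression matrices with planted SUVmax-linked genes, a grade
  confounder, and per-patient random intercepts over repeated timepoints.

All randomness flows through one explicit integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .cohortstats import SurvivalCohort
from .isocontour import DEFAULT_LEVELS, isocontours
from .volumes import UNIT_ACTIVITY, ImageVolume, InjectionRecord, Mask
from .wbt import ExpressionStudy

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_pet_phantom",
    "make_target_mask",
    "make_survival_cohort",
    "make_expression_study",
]


@dataclass
class PhantomSpec:
    """Recipe for one PET activity phantom.

    ``hotspots`` is a list of (center_voxel, sigma_mm_per_axis,
    peak_amplitude_kBq_per_ml); Gaussian widths are in millimetres so the
    phantom respects anisotropic voxel spacing.
    """

    grid_shape: tuple[int, int, int]
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_uptake: float = 1.0
    hotspots: list[tuple[tuple[int, int, int], tuple[float, float, float], float]] = field(
        default_factory=list
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be positive")
        if self.background_uptake < 0:
            raise ValueError("background_uptake must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for center, sigmas, amp in self.hotspots:
            if any(not 0 <= c < s for c, s in zip(center, self.grid_shape)):
                raise ValueError(f"hotspot center {tuple(center)} lies outside grid {tuple(self.grid_shape)}")
            if any(sg <= 0 for sg in sigmas):
                raise ValueError("hotspot sigmas must be positive")


@dataclass
class GroundTruth:
    """Known truths attached to a generated input, for recovery tests."""

    true_peak_activity: float | None = None
    true_suvmax: float | None = None
    true_isocontour_volumes_ml: dict[float, float] = field(default_factory=dict)
    planted_ci: dict[float, float] = field(default_factory=dict)
    true_cutoff: float | None = None
    true_effect_log_scale: float | None = None
    planted_genes: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for level, ci in self.planted_ci.items():
            if not 0 <= ci <= 1:
                raise ValueError(f"planted CI at level {level} outside [0, 1]")
        vols = [self.true_isocontour_volumes_ml[k]
                for k in sorted(self.true_isocontour_volumes_ml)]
        if any(b > a + 1e-9 for a, b in zip(vols, vols[1:])):
            raise ValueError("isocontour volumes must be non-increasing with level")


def _noise_free_phantom(spec: PhantomSpec) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in spec.grid_shape], indexing="ij")
    clean = np.full(spec.grid_shape, float(spec.background_uptake))
    for center, sigmas, amp in spec.hotspots:
        q = np.zeros(spec.grid_shape)
        for ax in range(3):
            d_mm = (grids[ax] - center[ax]) * spec.voxel_spacing_mm[ax]
            q += (d_mm / sigmas[ax]) ** 2
        clean += amp * np.exp(-0.5 * q)
    return clean


def make_pet_phantom(spec: PhantomSpec, injection: InjectionRecord,
                     levels_pct=DEFAULT_LEVELS) -> tuple[ImageVolume, GroundTruth]:
    """Generate one activity phantom plus its noise-free ground truth.

    Ground truth holds the noise-free peak activity, the SUVmax it implies
    under the given injection record, and the noise-free %-of-peak
    isocontour volumes over the whole grid.
    """
    clean = _noise_free_phantom(spec)
    rng = np.random.default_rng(spec.seed)
    values = clean
    if spec.noise_sd > 0:
        values = clean + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    values = np.clip(values, 0.0, None)

    peak = float(clean.max())
    voxvol = float(np.prod(spec.voxel_spacing_mm)) / 1000.0
    truth = GroundTruth(
        true_peak_activity=peak,
        true_suvmax=peak / (injection.injected_activity_MBq / injection.body_weight_kg),
        true_isocontour_volumes_ml={
            float(l): int((clean >= l / 100.0 * peak).sum()) * voxvol
            for l in sorted(levels_pct)
        },
    )
    vol = ImageVolume(values, spec.voxel_spacing_mm, UNIT_ACTIVITY)
    return vol, truth


def make_target_mask(pet: ImageVolume, roi: Mask, level_pct: float,
                     target_ci: float, seed: int = 0) -> Mask:
    """Build an MRI-target-like mask with a chosen conformity index.

    Starting from the %SUVmax isocontour at ``level_pct``, the mask is
    grown outward shell by shell (voxels within a shell added in seeded
    random order) until the Jaccard overlap with the isocontour — which for
    a superset is simply |iso| / |mask| — falls within +-0.05 of
    ``target_ci``. Because the result contains the isocontour, lower
    isocontour levels (larger volumes) can only match it better, making the
    construction suitable for planting a known best-matching level.
    """
    if not 0 < target_ci <= 1:
        raise ValueError("target_ci must lie in (0, 1]")
    iso = isocontours(pet, roi, [level_pct]).masks[float(level_pct)]
    if iso.is_empty():
        raise ValueError(f"isocontour at {level_pct}% of SUVmax is empty; target unreachable")
    if target_ci == 1:
        return Mask(iso.values.copy(), iso.voxel_spacing_mm, "mri_target", affine=iso.affine)

    n_iso = iso.voxel_count
    n_target = int(round(n_iso / target_ci))
    if n_target > iso.values.size:
        raise ValueError(
            f"target CI {target_ci} at level {level_pct}% needs {n_target} voxels "
            f"but the grid has only {iso.values.size}"
        )
    rng = np.random.default_rng(seed)
    mask = iso.values.copy()
    struct = ndimage.generate_binary_structure(3, 1)
    while mask.sum() < n_target:
        shell = ndimage.binary_dilation(mask, structure=struct) & ~mask
        if not shell.any():
            raise ValueError(
                f"cannot reach target CI {target_ci} at level {level_pct}%: "
                "grid exhausted while growing the mask"
            )
        idx = np.flatnonzero(shell.ravel())
        rng.shuffle(idx)
        need = n_target - int(mask.sum())
        flat = mask.ravel()
        flat[idx[:need]] = True
    return Mask(mask, iso.voxel_spacing_mm, "mri_target", affine=iso.affine)


def make_survival_cohort(n: int, cutoff: float, effect_log_scale: float,
                         shape: float = 2.0, scale_base: float = 12.0,
                         censor_rate: float = 0.2,
                         suv_range: tuple[float, float] = (1.0, 6.0),
                         seed: int = 0) -> SurvivalCohort:
    """Cohort whose event times follow the fitted log-logistic AFT law.

    SUVmax is uniform over ``suv_range``; event times are log-logistic with
    shape ``shape`` and scale exp(log(scale_base) - effect_log_scale *
    1[SUVmax > cutoff]) — so the log-logistic median of the low-uptake
    group is ``scale_base`` months. Censoring is independent uniform on
    (0, c) with c solved so the expected censored fraction matches
    ``censor_rate`` (non-informative by construction).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if suv_range[0] >= suv_range[1]:
        raise ValueError("suv_range must satisfy min < max")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    if shape <= 0 or scale_base <= 0:
        raise ValueError("shape and scale_base must be positive")
    rng = np.random.default_rng(seed)
    suv = rng.uniform(*suv_range, size=n)
    alpha = scale_base * np.exp(-effect_log_scale * (suv > cutoff))
    u = rng.uniform(size=n)
    t_event = alpha * (u / (1.0 - u)) ** (1.0 / shape)  # inverse CDF

    if censor_rate == 0:
        return SurvivalCohort(time=t_event, event=np.ones(n, bool), suvmax=suv)

    # P(censored | c) = mean_i min(T_i / c, 1), decreasing in c
    def censored_frac(c: float) -> float:
        return float(np.minimum(t_event / c, 1.0).mean())

    lo, hi = 1e-6, float(t_event.max()) * 2
    c = optimize.brentq(lambda c: censored_frac(c) - censor_rate, lo, hi)
    t_cens = rng.uniform(0.0, c, size=n)
    event = t_event <= t_cens
    time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-9)
    return SurvivalCohort(time=time, event=event, suvmax=suv)


def make_expression_study(n_genes: int, n_samples: int, n_planted: int,
                          beta: float, grade_confounding: float = 0.0,
                          n_timepoints_per_patient: int = 1, seed: int = 0,
                          residual_sd: float = 1.0,
                          patient_sd: float = 0.5) -> ExpressionStudy:
    """Expression matrix with planted SUVmax-linked genes and a grade confounder.

    Planted genes carry slope ``beta`` on SUVmax; every gene receives a
    grade main effect scaled by ``grade_confounding`` and a per-patient
    Gaussian random intercept (sd ``patient_sd``) shared across that
    patient's timepoints. SUVmax has a grade-dependent mean, so grade
    genuinely confounds the marginal SUVmax association.
    """
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    if n_samples < 3:
        raise ValueError("need at least 3 samples for downstream model fits")
    if n_timepoints_per_patient < 1:
        raise ValueError("n_timepoints_per_patient must be >= 1")
    rng = np.random.default_rng(seed)

    n_patients = -(-n_samples // n_timepoints_per_patient)  # ceil
    patient_of = np.arange(n_samples) // n_timepoints_per_patient
    timepoint = np.arange(n_samples) % n_timepoints_per_patient

    grade_p = rng.choice([2, 3, 4], size=n_patients)
    suv_p = np.clip(3.0 + 0.7 * (grade_p - 3) + rng.normal(0, 0.8, n_patients), 0.5, None)
    grade = grade_p[patient_of].astype(float)
    suv = suv_p[patient_of]

    genes = [f"G{i:05d}" for i in range(n_genes)]
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    slope = np.zeros(n_genes)
    slope[planted_idx] = beta

    mu_g = rng.normal(8.0, 2.0, n_genes)
    gamma_g = rng.normal(0.0, 1.0, n_genes)
    u_gp = rng.normal(0.0, patient_sd, (n_genes, n_patients))
    eps = rng.normal(0.0, residual_sd, (n_genes, n_samples))

    X = (
        mu_g[:, None]
        + slope[:, None] * suv[None, :]
        + grade_confounding * gamma_g[:, None] * grade[None, :]
        + u_gp[:, patient_of]
        + eps
    )
    sample_ids = [f"S{patient_of[i]:03d}T{timepoint[i]}" for i in range(n_samples)]
    expr = pd.DataFrame(X, index=genes, columns=sample_ids)
    samples = pd.DataFrame({
        "suvmax": suv,
        "initial_grade": grade.astype(int),
        "patient_id": [f"P{p:03d}" for p in patient_of],
        "timepoint": timepoint,
    }, index=sample_ids)
    return ExpressionStudy(expr, samples,
                           planted_genes=[genes[i] for i in sorted(planted_idx)])
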