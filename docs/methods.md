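# Methods

This note documents the models and procedures the package implements, the
design choices made where conventions were genuinely open, what the
synthetic generators do and do not emulate, and the numerical details a
user re-running the analyses should know.

## SUV and SUR quantification

SUV is computed voxel-wise as activity concentration divided by injected
dose per body weight (the body-weight convention, tissue density 1 g/ml,
so SUV is dimensionless). Inputs are assumed decay-corrected to injection
time, the usual DICOM convention; when a scan is flagged otherwise, the
activity is multiplied by `exp(ln2·Δt / T½)` with Δt the
injection-to-acquisition interval in minutes and T½ = 109.77 min for F-18.
Lean-body-mass or body-surface-area variants are deliberately not
provided: the body-weight form is the universal default and nothing in
the analysis depends on the variant, only on consistency.

SUVmax is taken over a caller-supplied tumor ROI; high-uptake non-tumor
structures (vessels, basal ganglia) are handled by excluding them from the
ROI rather than by post-hoc masking, which keeps the operation a pure
maximum. SURmax divides SUVmax by the arithmetic mean SUV of a
caller-supplied background reference mask that must be disjoint from the
ROI. No automatic contralateral mirroring is attempted — a deterministic,
caller-controlled reference keeps the metric testable.

## Isocontours

`I_x` keeps every ROI voxel with SUV at least x% of the ROI's SUVmax. The
threshold is inclusive (`≥`), so `I_100` always contains the argmax
voxel(s) and no level within (0, 100] can be empty for a non-empty ROI.
No connected-component pruning or hole-filling is applied; satellite
supra-threshold voxels inside the ROI are retained. Volumes are voxel
count × voxel volume, reported in ml (≡ cm³). Because thresholds are
relative to SUVmax, isocontours are invariant to positive rescaling of
the image — they can equally be computed on raw activity.

## Concordance

The conformity index is the Jaccard overlap of the PET isocontour and the
MRI-based treatment volume; Dice follows from the identity
`D = 2J/(1+J)` and both are computed from integer voxel counts, so they
agree exactly with a brute-force count. Added volume is union − MRIvol
and the percent increase uses MRIvol as the denominator (the clinically
relevant question being how much the treated volume would grow). The best
matching isocontour is the CI argmax over levels; ties break toward the
smallest level, i.e. the largest volume — the conservative choice for
target coverage. Inputs on different grids are harmonized by
nearest-neighbour resampling through the voxel-to-world affines (rigid
registration itself is out of scope; images are assumed co-registered).
Nearest-neighbour rather than linear interpolation preserves mask
binarity without introducing a second threshold.

## Feature matrix and grade ranking

Per patient, each level contributes seven overlap features (isocontour
volume, intersection, union, CI, Dice, added volume, % increase), plus
MRIvol, SUVmax and SURmax — 31 columns at the standard four levels. The
matrix is emitted both raw and z-scaled (population SD; constant columns
flagged and excluded from scaling).

Grade separation is ranked by resampled random forests: each of 200
resamples draws a stratified 80% of patients without replacement, fits a
forest (100 trees) on the unscaled features, and measures permutation
importance (accuracy drop, 5 shuffles per feature) on the held-out 20%.
Permutation importance on held-out data was chosen over impurity
importance because the latter is biased toward high-cardinality features.
Reported are each feature's mean importance and its top-rank frequency.
One caveat is worth stating: the resamples share a single cohort, so
top-rank frequencies are not independent draws — in a small cohort
(n ≈ 20) a noise feature that is chance-correlated with grade can
top-rank in well over 30% of resamples in some realizations. Frequencies
should be read as "dominance within this cohort", not as significance.

Two-group comparisons use the Wilcoxon rank-sum test: exact enumeration
when n₁+n₂ ≤ 12 with no ties, otherwise the normal approximation with
tie-corrected variance and no continuity correction (so identical samples
give p = 1 exactly).

## Survival models and the optimal-cutoff scan

The log-logistic AFT model has survival `S(t|x) = 1/(1+(t/α(x))^β)` with
`log α(x) = μ + xᵀθ`; the median survival time equals α(x). The
right-censored log-likelihood is maximized over (μ, θ, log β) by L-BFGS
with the analytic gradient; standard errors come from the numerically
differentiated observed information and p-values are Wald-type. Effects
are reported as `exp(−θ)`, oriented so values above 1 mean worse
(accelerated) survival; the model's own transformation to an odds ratio is
deliberately labelled an analogue, since the survival odds interpretation
holds exactly only at fixed time points.

The Cox model maximizes the partial likelihood with Breslow handling of
tied event times (exact likelihood handles ties in the parametric model).
Monotone likelihoods (perfect separation in risk sets) are detected by
coefficient divergence and reported as an error advising penalization.

The median split dichotomizes at the sample median with a strict `>` for
the high group. The optimal-cutoff scan evaluates the binary split
`1[SUVmax > c]` at every midpoint between consecutive distinct observed
values that leaves at least `min_group` (default 5) subjects per side, and
selects the cutoff with the smallest Wald p (ties toward the smaller
cutoff). **No multiplicity adjustment is applied inside the scan** — this
mirrors the minimal-p-value practice the procedure models, and the
selection is strongly optimistic: on null cohorts (no true effect,
n = 80) the pre-specified median-cutoff test rejects at ~5% as it should,
while the scan's minimum p falls below 0.05 in over half of replicates.
The full per-cutoff trace is emitted so users can apply a correction or a
resampling calibration. A related accuracy caveat: the argmin-p estimate
of a true change point is noisy at realistic effect sizes — at effect 0.8
on the log scale and n = 120 its median error is ~0.1 SUV units (several
grid steps), so single-cohort "optimal" cutoffs should be reported with
that uncertainty in mind.

## Transcriptome association

Genes are filtered by raw MAD (median absolute deviation from the gene
median, no 1.4826 scaling — scaling cannot change the ranking), keeping
the top fraction with boundary ties broken by gene id. Per gene, ordinary
least squares regresses expression on SUVmax plus initial WHO grade coded
numerically (2/3/4), matching the ordinal usage; a factor coding is
available via a switch. Samples are individual blood draws: repeated
timepoints enter as separate rows, which overstates the effective sample
size of the per-gene screen — this is accepted for the screen and handled
rigorously only in the panel models. Multiplicity is controlled by
Bonferroni and Benjamini–Hochberg over the tested (non-constant) genes.

Checkpoint-panel genes with repeated timepoints get a linear model with a
Gaussian per-patient random intercept, fitted by REML profiled down to the
single variance ratio λ = σ²_patient/σ²_residual (1-D bounded
optimization, with the λ = 0 boundary checked explicitly, where the fit
reduces exactly to OLS). Inference on the SUVmax slope uses a t reference
whose degrees of freedom respect the design: SUVmax is constant within
patient, so patients are the effective units and df = n_patients − 2; a
normal reference was measurably anti-conservative at 8–12 patients. When
no patient has repeated timepoints the random intercept is unidentifiable
and the fit falls back to OLS with a warning.

## Synthetic generators: what they emulate, and what not

The phantom module generates every input with known truth:

* **PET phantoms** — tissue background plus anisotropic Gaussian hotspots
  (widths in mm, so anisotropic voxels are respected) plus i.i.d.
  Gaussian noise, clipped at zero. This is sufficient to stress maximum
  statistics and threshold segmentation. It does **not** model scanner
  physics: no point-spread function, attenuation, partial-volume effect or
  reconstruction correlation. Passing tests therefore validate the
  arithmetic and the statistics, not robustness to PET reconstruction
  artefacts.
* **Target masks** — built by growing the chosen isocontour outward,
  dilation shell by dilation shell (voxels within a shell added in seeded
  random order) until the Jaccard with the isocontour hits the requested
  conformity index ±0.05. Since the result is a superset of the chosen
  isocontour, any higher level can only match it worse, making the planted
  best level recoverable by construction.
* **Survival cohorts** — SUVmax uniform over (1, 6) (mirroring the
  clinical SUVmax range), event times log-logistic with shape 2 and
  low-group scale 12 months, the scale divided by `exp(effect)` above the
  true cutoff; censoring is independent uniform on (0, c) with c solved
  numerically so the expected censored fraction matches the requested rate
  (default 0.2). Censoring is non-informative by construction.
* **Expression studies** — Gaussian log-intensity-like matrices with
  planted SUVmax slopes, a per-gene grade effect scaled by a confounding
  knob, per-patient random intercepts shared across timepoints, and a
  grade-dependent SUVmax mean so grade genuinely confounds the marginal
  association.

All generators are driven by one explicit seed per call; identical
arguments give byte-identical outputs.

## Pipeline and problem sizes

The `run` pipeline executes phantom → SUV → isocontours → concordance →
features → survival → transcriptome from one JSON config, communicating
only through files, and writes a manifest with the package version, seeds
and SHA-256 hashes of every table, so reruns are verifiably reproducible
and any stage can be re-run alone. The bundled demo uses 10–12 patients on
24³–32³ grids, a survival cohort of 80–120, and a 150–400 × 18–27
expression study — sizes chosen so the full chain, the test suite, and the
acceptance script each complete in minutes on a single CPU while leaving
every statistical check adequately powered.

## Known limitations

* Static uptake only; dynamic (time–activity) FET analysis is out of
  scope, as are SUVpeak/SUVmean tumor metrics.
* Registration is assumed done; only grid harmonization is provided.
* The minimal-p cutoff scan is faithful to practice but anti-conservative
  by design; see above.
* The per-gene screen treats repeated blood draws as independent; only
  the panel models account for within-patient correlation.
* Phantom realism is deliberately limited to what the tested statistics
  need.
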