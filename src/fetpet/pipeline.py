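"""End-to-end pipeline orchestration with a JSON config and manifest.

A run executes, as configured: phantom generation (optional) -> SUV
quantification -> isocontours -> concordance -> feature ranking -> survival
analysis -> transcriptome association. Every stage communicates only
through files in the output directory; a JSON manifest records package
version, seeds, SHA-256 hashes and per-stage outputs so any downstream
stage can be re-run alone and reproduce its results exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from importlib.metadata import version as _dist_version

from .cohortstats import SurvivalCohort, median_split, scan_cutoffs, univariate_table
from .concordance import best_matching_isocontour, resample_to_grid
from .features import assemble_features, rank_features_by_grade
from .isocontour import isocontours
from .phantom import (
    PhantomSpec,
    make_expression_study,
    make_pet_phantom,
    make_survival_cohort,
    make_target_mask,
)
from .suvquant import surmax, to_suv
from .volumes import InjectionRecord, Mask, load_image, load_mask, save_volume
from .wbt import ExpressionStudy, associate_genes, mad_filter, mixed_checkpoint_model

log = logging.getLogger("fetpet")

STAGES = ("phantom", "suv", "contours", "concord", "features", "survive", "wbt")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``phantom`` (generator settings; the demo path) or ``inputs``
    (paths to existing NIfTI/CSV data) must be present. All referenced
    paths are checked at validation time, before any computation.
    """

    outdir: Path
    seed: int = 0
    levels_pct: list[float] = field(default_factory=lambda: [40, 50, 60, 70])
    min_group: int = 5
    mad_top_fraction: float = 0.10
    phantom: dict | None = None
    inputs: dict | None = None
    verbosity: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        known = {"outdir", "seed", "levels_pct", "min_group", "mad_top_fraction",
                 "phantom", "inputs", "verbosity"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError("config must set 'outdir'")
        cfg = cls(**{**raw, "outdir": base / raw["outdir"]})
        cfg.validate(base)
        return cfg

    def validate(self, base: Path = Path(".")) -> None:
        levels = [float(l) for l in self.levels_pct]
        if levels != sorted(levels) or not levels:
            raise ValueError("levels_pct must be a non-empty ascending list")
        if any(l <= 0 or l > 100 for l in levels):
            raise ValueError("levels_pct entries must lie in (0, 100]")
        self.levels_pct = levels
        if self.min_group < 1:
            raise ValueError("min_group must be >= 1")
        if not 0 < self.mad_top_fraction <= 1:
            raise ValueError("mad_top_fraction must lie in (0, 1]")
        if (self.phantom is None) == (self.inputs is None):
            raise ValueError("config must set exactly one of 'phantom' or 'inputs'")
        if self.inputs is not None:
            for patient in self.inputs.get("patients", []):
                for key in ("pet", "roi", "reference", "mri", "injection"):
                    p = base / patient[key]
                    if not p.exists():
                        raise ValueError(f"missing input path for {patient.get('id')}: {p}")
                patient["_base"] = str(base)
            for key in ("cohort_csv", "expression_csv", "samples_csv"):
                if key in self.inputs and not (base / self.inputs[key]).exists():
                    raise ValueError(f"missing input path: {base / self.inputs[key]}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\n")


DEFAULT_PHANTOM = {
    "n_patients": 12,
    "grid_shape": [32, 32, 32],
    "voxel_spacing_mm": [2.0, 2.0, 2.0],
    "background_uptake": 1.0,
    "noise_sd": 0.3,
    "target_level_pct": 40,
    "survival": {"n": 120, "cutoff": 3.0, "effect_log_scale": 0.8},
    "expression": {"n_genes": 400, "n_samples": 27, "n_planted": 20,
                   "beta": 0.8, "grade_confounding": 0.5,
                   "n_timepoints_per_patient": 3},
}


def _stage_phantom(cfg: RunConfig, outdir: Path) -> dict:
    """Generate a full synthetic study: per-patient imaging + cohort + expression."""
    p = {**DEFAULT_PHANTOM, **(cfg.phantom or {})}
    rng = np.random.default_rng(cfg.seed)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    shape = tuple(int(s) for s in p["grid_shape"])
    spacing = tuple(float(s) for s in p["voxel_spacing_mm"])
    patients = []
    for i in range(int(p["n_patients"])):
        pid = f"PT{i:03d}"
        pseed = int(rng.integers(0, 2**31 - 1))
        prng = np.random.default_rng(pseed)
        center = tuple(int(prng.integers(s // 2 - 3, s // 2 + 4)) for s in shape)
        sigmas = tuple(float(prng.uniform(5.0, 9.0)) for _ in range(3))
        amp = float(prng.uniform(5.0, 12.0))
        spec = PhantomSpec(shape, spacing, float(p["background_uptake"]),
                           [(center, sigmas, amp)], float(p["noise_sd"]), seed=pseed)
        inj = InjectionRecord(
            injected_activity_MBq=float(prng.uniform(150, 250)),
            body_weight_kg=float(prng.uniform(55, 95)),
            injection_time=datetime(2020, 1, 1, 10, 0),
            acquisition_time=datetime(2020, 1, 1, 10, 12),
        )
        pet, truth = make_pet_phantom(spec, inj, cfg.levels_pct)
        # ROI: central box around the hotspot; reference: disjoint corner slab
        roi = np.zeros(shape, bool)
        sl = tuple(slice(max(c - 10, 0), min(c + 11, s)) for c, s in zip(center, shape))
        roi[sl] = True
        ref = np.zeros(shape, bool)
        ref[:4, :4, :] = True
        ref &= ~roi
        roi_m = Mask(roi, spacing, "roi")
        target_ci = float(prng.uniform(0.25, 0.6))
        mri = make_target_mask(pet, roi_m, float(p["target_level_pct"]), target_ci,
                               seed=pseed + 1)
        paths = {
            "pet": indir / f"{pid}_pet.nii.gz",
            "roi": indir / f"{pid}_roi.nii.gz",
            "reference": indir / f"{pid}_ref.nii.gz",
            "mri": indir / f"{pid}_mri.nii.gz",
            "injection": indir / f"{pid}_injection.json",
        }
        save_volume(pet, paths["pet"])
        save_volume(roi_m, paths["roi"])
        save_volume(Mask(ref, spacing, "reference"), paths["reference"])
        save_volume(mri, paths["mri"])
        inj.to_json(paths["injection"])
        patients.append({
            "id": pid, "grade": 3 + i % 2, "seed": pseed,
            "planted_ci": target_ci, "true_suvmax": truth.true_suvmax,
            **{k: str(v) for k, v in paths.items()},
        })
    surv = {**DEFAULT_PHANTOM["survival"], **p.get("survival", {})}
    cohort = make_survival_cohort(seed=int(rng.integers(0, 2**31 - 1)), **surv)
    cohort_path = indir / "cohort.csv"
    _write_csv(cohort.to_frame(), cohort_path)
    expr_cfg = {**DEFAULT_PHANTOM["expression"], **p.get("expression", {})}
    study = make_expression_study(seed=int(rng.integers(0, 2**31 - 1)), **expr_cfg)
    expr_path = indir / "expression.csv"
    samples_path = indir / "samples.csv"
    study.expr.to_csv(expr_path, lineterminator="\n")
    study.samples.to_csv(samples_path, index_label="sample_id", lineterminator="\n")
    relative_patients = [
        {k: (Path(v).name if k in ("pet", "roi", "reference", "mri", "injection") else v)
         for k, v in rec.items()}
        for rec in patients
    ]
    (indir / "ground_truth.json").write_text(json.dumps({
        "patients": relative_patients,
        "survival": surv,
        "expression": {**expr_cfg, "planted_genes": study.planted_genes},
    }, indent=2) + "\n")
    return {
        "patients": patients,
        "cohort_csv": str(cohort_path),
        "expression_csv": str(expr_path),
        "samples_csv": str(samples_path),
        "checkpoint_genes": study.planted_genes[:5],
        "outputs": [str(indir / "ground_truth.json"), str(cohort_path), str(expr_path)],
    }


def _load_patient(rec: dict):
    base = Path(rec.get("_base", "."))
    pet = load_image(base / rec["pet"])
    roi = load_mask(base / rec["roi"], "roi")
    ref = load_mask(base / rec["reference"], "reference")
    mri = load_mask(base / rec["mri"], "mri_target")
    inj = InjectionRecord.from_json(base / rec["injection"])
    return pet, roi, ref, mri, inj


def _stage_suv(cfg: RunConfig, outdir: Path, patients: list[dict]) -> dict:
    rows = []
    suv_volumes = {}
    for rec in patients:
        pet, roi, ref, _, inj = _load_patient(rec)
        suv = to_suv(pet, inj)
        m = surmax(suv, roi, ref)
        suv_volumes[rec["id"]] = (suv, roi, ref)
        rows.append({"patient": rec["id"], "suvmax": m.suvmax,
                     "ref_mean_suv": m.ref_mean_suv, "surmax": m.surmax})
    path = outdir / "uptake_metrics.csv"
    _write_csv(pd.DataFrame(rows), path)
    return {"metrics_csv": str(path), "suv_volumes": suv_volumes, "outputs": [str(path)]}


def _stage_contours(cfg: RunConfig, outdir: Path, suv_volumes: dict) -> dict:
    rows = []
    iso_sets = {}
    for pid, (suv, roi, _) in suv_volumes.items():
        iso = isocontours(suv, roi, cfg.levels_pct)
        iso_sets[pid] = iso
        for level in iso.levels_pct:
            rows.append({"patient": pid, "level_pct": level,
                         "volume_ml": iso.volumes_ml[level]})
    path = outdir / "isocontour_volumes.csv"
    _write_csv(pd.DataFrame(rows), path)
    return {"volumes_csv": str(path), "iso_sets": iso_sets, "outputs": [str(path)]}


def _stage_concord(cfg: RunConfig, outdir: Path, patients: list[dict],
                   iso_sets: dict) -> dict:
    tables = []
    frames = []
    for rec in patients:
        _, _, _, mri, _ = _load_patient(rec)
        iso = iso_sets[rec["id"]]
        ref_mask = iso.masks[iso.levels_pct[0]]
        mri = resample_to_grid(mri, ref_mask)
        table = best_matching_isocontour(iso, mri, patient=rec["id"])
        tables.append(table)
        frames.append(table.to_frame())
    path = outdir / "concordance.csv"
    _write_csv(pd.concat(frames, ignore_index=True), path)
    return {"concordance_csv": str(path), "tables": tables, "outputs": [str(path)]}


def _stage_features(cfg: RunConfig, outdir: Path, patients: list[dict],
                    tables: list, metrics_csv: str) -> dict:
    metrics_df = pd.read_csv(metrics_csv).set_index("patient")
    from .suvquant import UptakeMetrics
    metrics = {pid: UptakeMetrics(r["suvmax"], r["ref_mean_suv"], r["surmax"])
               for pid, r in metrics_df.iterrows()}
    grades = {rec["id"]: int(rec["grade"]) for rec in patients}
    fm = assemble_features(tables, metrics, grades)
    fpath = outdir / "feature_matrix.csv"
    fm.data.assign(grade=fm.grade).to_csv(fpath, index_label="patient", lineterminator="\n")
    ranking = rank_features_by_grade(fm, n_resamples=200, seed=cfg.seed)
    rpath = outdir / "feature_ranking.csv"
    ranking.to_csv(rpath, lineterminator="\n")
    return {"feature_matrix_csv": str(fpath), "ranking_csv": str(rpath),
            "outputs": [str(fpath), str(rpath)]}


def _stage_survive(cfg: RunConfig, outdir: Path, cohort_csv: str) -> dict:
    cohort = SurvivalCohort.from_frame(pd.read_csv(cohort_csv))
    med_cut, _high = median_split(cohort)
    scan = scan_cutoffs(cohort, model="loglogistic_aft", min_group=cfg.min_group)
    tpath = outdir / "cutoff_scan.csv"
    _write_csv(scan.trace, tpath)
    candidates = [c for c in cohort.covariates.columns] or []
    uni, selected = (univariate_table(cohort, candidates)
                     if candidates else (pd.DataFrame(), []))
    summary = {
        "median_cutoff": med_cut,
        "optimal_cutoff": scan.optimal_cutoff,
        "optimal_p": scan.optimal_p,
        "n": cohort.n,
        "n_events": int(cohort.event.sum()),
        "univariate_selected": selected,
    }
    spath = outdir / "survival_summary.json"
    spath.write_text(json.dumps(summary, indent=2) + "\n")
    return {"scan_csv": str(tpath), "summary_json": str(spath),
            "outputs": [str(tpath), str(spath)]}


def _stage_wbt(cfg: RunConfig, outdir: Path, expression_csv: str,
               samples_csv: str, checkpoint_genes: list[str]) -> dict:
    expr = pd.read_csv(expression_csv, index_col=0)
    samples = pd.read_csv(samples_csv, index_col="sample_id")
    study = ExpressionStudy(expr, samples)
    kept = mad_filter(study, cfg.mad_top_fraction)
    table = associate_genes(kept)
    apath = outdir / "gene_association.csv"
    table.to_csv(apath, index_label="gene", lineterminator="\n")
    outputs = [str(apath)]
    result = {"association_csv": str(apath)}
    genes = [g for g in checkpoint_genes if g in study.expr.index]
    if genes:
        mixed = mixed_checkpoint_model(study, genes)
        cpath = outdir / "checkpoint_mixed.csv"
        mixed.to_csv(cpath, lineterminator="\n")
        outputs.append(str(cpath))
        result["checkpoint_csv"] = str(cpath)
    return {**result, "outputs": outputs}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a JSON manifest.

    Returns the manifest dict; raises :class:`PipelineError` naming the
    failing stage on any error (nothing after the failing stage runs).
    """
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, config.verbosity, 20),
                        format="%(name)s %(levelname)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _dist_version("fetpet"),
        "seed": config.seed,
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "stages": {},
    }
    state: dict = {}

    def run_stage(name: str, fn, *args, **kwargs):
        log.info("[%s] starting", name)
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # abort naming the stage
            raise PipelineError(name, str(exc)) from exc
        outputs = result.pop("outputs", [])
        manifest["stages"][name] = {
            "status": "complete",
            "outputs": {str(Path(o).name): _sha256(Path(o)) for o in outputs},
        }
        state.update(result)
        log.info("[%s] complete", name)

    if config.phantom is not None:
        run_stage("phantom", _stage_phantom, config, outdir)
        patients = state["patients"]
    else:
        patients = config.inputs.get("patients", [])
        state["cohort_csv"] = str(Path(config.inputs.get("_base", ".")) /
                                  config.inputs["cohort_csv"]) \
            if "cohort_csv" in config.inputs else None
        for key in ("cohort_csv", "expression_csv", "samples_csv"):
            if key in config.inputs:
                state[key] = str(config.inputs[key])
        state["checkpoint_genes"] = config.inputs.get("checkpoint_genes", [])
        manifest["stages"]["phantom"] = {"status": "skipped (user inputs)", "outputs": {}}

    if patients:
        run_stage("suv", _stage_suv, config, outdir, patients)
        run_stage("contours", _stage_contours, config, outdir, state["suv_volumes"])
        run_stage("concord", _stage_concord, config, outdir, patients, state["iso_sets"])
        run_stage("features", _stage_features, config, outdir, patients,
                  state["tables"], state["metrics_csv"])
    if state.get("cohort_csv"):
        run_stage("survive", _stage_survive, config, outdir, state["cohort_csv"])
    if state.get("expression_csv"):
        run_stage("wbt", _stage_wbt, config, outdir, state["expression_csv"],
                  state["samples_csv"], state.get("checkpoint_genes", []))

    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
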