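{
  "outdir": "../scratch/demo_run",
  "seed": 11,
  "levels_pct": [40, 50, 60, 70],
  "min_group": 5,
  "mad_top_fraction": 0.1,
  "phantom": {
    "n_patients": 10,
    "grid_shape": [24, 24, 24],
    "voxel_spacing_mm": [2.0, 2.0, 2.0],
    "background_uptake": 1.0,
    "noise_sd": 0.3,
    "target_level_pct": 40,
    "survival": {"n": 120, "cutoff": 3.0, "effect_log_scale": 0.8},
    "expression": {
      "n_genes": 400, "n_samples": 27, "n_planted": 20,
      "beta": 0.8, "grade_confounding": 0.5, "n_timepoints_per_patient": 3
    }
  }
}
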