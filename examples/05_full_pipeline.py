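"""Run the whole pipeline from one config and inspect the manifest.

Equivalent to `fetpet run --config examples/demo_config.json`: generates a
synthetic study (10 patients of PET + masks, a survival cohort, an
expression study), then runs SUV -> isocontours -> concordance -> feature
ranking -> cutoff scan -> gene association, writing CSVs and a manifest
under out/.
"""

import json
from pathlib import Path

from fetpet import RunConfig, run_pipeline

cfg = RunConfig.from_json(Path(__file__).parent / "demo_config.json")
manifest = run_pipeline(cfg)

print("stages:")
for name, info in manifest["stages"].items():
    print(f"  {name:10s} {info['status']}  ({len(info['outputs'])} outputs)")

out = Path(cfg.outdir)
summary = json.loads((out / "survival_summary.json").read_text())
print(f"\nsurvival: median cutoff {summary['median_cutoff']:.2f}, "
      f"optimal cutoff {summary['optimal_cutoff']:.2f} "
      f"(p {summary['optimal_p']:.2e})")

import pandas as pd
ranking = pd.read_csv(out / "feature_ranking.csv").head(3)
print("\ntop grade-separating features:")
print(ranking.to_string(index=False))
print(f"\nall tables and seeds are recorded in {out / 'manifest.json'};")
print("rerunning with the same config reproduces every CSV byte for byte.")
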