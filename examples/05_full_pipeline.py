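"""One-call pipeline: screen -> VIF/PCA selection -> validated LDA models.

Equivalent to `glycomark pipeline --seed 7` on the command line.
"""

import json

from glycomark import PipelineConfig, run_pipeline
from glycomark.synthdata import CohortConfig

cfg = PipelineConfig(seed=7, vif_runs=200, cohort=CohortConfig(seed=7))
report = run_pipeline(cfg)

print(f"config {report['provenance']['config_hash']} "
      f"(seed {report['provenance']['seed']})")
print(f"{report['n_significant']} features significant after Holm control")
print(f"PCA retains {report['pca']['k']} components")
for entry in report["validation"]:
    loo = entry["loocv"]
    line = (f"{entry['model']:>6s}: LOOCV Ac {loo['accuracy']}% "
            f"Sp {loo['specificity']}% Sn {loo['sensitivity']}%")
    if "subsample" in entry:
        sub = entry["subsample"]
        line += (f" | sub-sample Ac {sub['accuracy']}% "
                 f"Sp {sub['specificity']}% Sn {sub['sensitivity']}%")
    print(line)

with open("pipeline_report.json", "w") as fh:
    json.dump(report, fh, indent=2)
print("full report written to pipeline_report.json")
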