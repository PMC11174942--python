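"""The full measurement flow: simulate, calibrate, estimate, evaluate.

Library equivalent of the CLI round trip — synthesize a trace and a
cohort, fit the per-BMI-stratum parameter table, run one non-contact
measurement, and score cohort-level agreement.
"""

import tempfile
from pathlib import Path

import numpy as np

from rppgbp import estimate_bp, evaluate_metrics, read_cohort_csv
from rppgbp.pipeline import RunConfig, calibrate, estimate, simulate

workdir = Path(tempfile.mkdtemp())
config = RunConfig(fps=30.0, duration_s=10, n_subjects_per_interval=8,
                   expansion_target=1, seed=4)

paths = simulate(config, workdir)
config.cohort_csv = paths["cohort_csv"]
table = calibrate(config, workdir)
print(f"calibrated {len(table.intervals)} BMI strata over {table.domain}")

config.trace_csv = paths["trace_csv"]
config.param_table_csv = str(workdir / "param_table.csv")
report = estimate(config, height_m=1.75, weight_kg=70.0)
print(f"BMI {report['bmi']:.2f}: SBP {report['sbp_mmhg']} mmHg, "
      f"DBP {report['dbp_mmhg']} mmHg "
      f"(E_peak {report['e_peak']:.3f}, E_valley {report['e_valley']:.3f})")

# cohort-level agreement of the fitted table against the references
cohort = read_cohort_csv(config.cohort_csv)
for kind in ("sbp", "dbp"):
    pred = [estimate_bp(table.lookup(r.bmi, kind), r.feature(kind), r.bmi) for r in cohort]
    ref = [r.reference(kind) for r in cohort]
    m = evaluate_metrics(ref, pred)
    print(f"{kind.upper()} over {len(cohort)} subjects: "
          f"MAPE {m.mape:.2f}%, RMSE {m.rmse:.2f} mmHg, R^2 {m.r2:.3f}")
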