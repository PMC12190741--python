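"""The full strategy factorial at reduced scale, with Table-style output.

Runs reference kinds x ploidy modes for small XX and XY cohorts and prints
the per-region TP/FP/FN table plus the headline summary metrics.
"""

import warnings

import pandas as pd

from sexchrom_varbench.bench import ExperimentConfig, run_experiment

warnings.filterwarnings("ignore", message="multi-allelic column")
pd.set_option("display.width", 120)

cfg = ExperimentConfig(n_xx=4, n_xy=4)
report = run_experiment(cfg, seed=11)

table = report.counts_table()
agg = (
    table[table["chrom"].isin(["X", "Y"])]
    .groupby(["cohort", "reference", "ploidy_mode", "chrom", "region"], sort=True)[
        ["TP", "FP", "FN"]
    ]
    .mean()
    .round(1)
)
print("per-sample means by strategy cell and region:")
print(agg)

print("\nsummary metrics:")
for key, value in report.summary.items():
    print(f"  {key}: {value:.3f}")

print(
    "\nReading the table: under the default reference the PAR rows have zero "
    "true positives (multi-mapping collapse); the complement-matched "
    "references recover them. Masking the Y XTR floods the X XTR with false "
    "positives. Y-chromosome rows are identical between default and SCC "
    "alignment."
)
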