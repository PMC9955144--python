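#!/usr/bin/env python
"""End-to-end analysis of the mechanistic cohort.

Reads the cohort written by 02_simulate_cohorts.py, runs the full pipeline
(eligibility filter, per-patient indices, subtype adjudication, group
statistics, rank-sum comparisons, ROC tables) and writes the report plus a
confusion matrix of called vs true subtype under results/cohort_report/.
"""

from pathlib import Path

import pandas as pd

from avslat import read_cohort, run_pipeline, write_report

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort_mechanistic.csv")
    report = run_pipeline(cohort)
    out = RESULTS / "cohort_report"
    write_report(report, out)

    pp = report.per_patient
    confusion = pd.crosstab(pp.true_subtype, pp.call, dropna=False)
    confusion.to_csv(out / "confusion_matrix.csv")
    print("confusion matrix (rows: true, cols: called):")
    print(confusion.to_string())
    agree = (pp.true_subtype == pp.call).mean()
    print(f"\nagreement: {agree:.1%} of {len(pp)} patients")
    print(f"report written to {out}")


if __name__ == "__main__":
    main()
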