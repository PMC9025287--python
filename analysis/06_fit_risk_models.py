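"""Build the habitat risk score and compare the five risk models.

Fits the Cox-LASSO HRS on the development habitat features, freezes its
coefficients, baseline-hazard constant and median cutoff, then builds
and evaluates all five risk models (two whole-tumour radiomics
comparators, HRS-only, clinical, combined clinical+HRS) on both
cohorts: high/low-risk hazard ratios, Harrell's C, and bootstrap model
comparisons against the combined model.
"""

from pathlib import Path

import pandas as pd

from habitatpipe import pipeline as pl
from habitatpipe import survival as sv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = pl.PipelineConfig.from_json(RESULTS / "config.json")
    pl.run_stage("fit", config)
    pl.run_stage("evaluate", config)

    hrs = sv.CoxLassoModel.from_json(
        Path(config.out_dir) / "fit" / "hrs_model.json"
    )
    print(f"HRS model: lambda = {hrs.lambda_:.4g}, h0(0) = {hrs.h0:.4g}, "
          f"median cutoff = {hrs.cutoff:.4g}")
    print("selected features:")
    for name, beta in zip(hrs.feature_names, hrs.coefficients):
        print(f"  {name}: {beta:+.3f}")

    report = pd.read_csv(
        Path(config.out_dir) / "evaluate" / "risk_model_report.csv"
    )
    cols = ["model", "cohort", "hazard_ratio", "hr_p", "c_index", "comparison_p"]
    print(report[cols].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
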