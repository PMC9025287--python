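"""Conform both cohorts to a common grid and intensity scale.

Resamples every study to 1 mm isotropic resolution (cubic B-spline for
the phases, nearest neighbour for the ROI) and histogram-matches the
validation cohort's intensities to the development cohort's pooled
tumour-ROI reference, phase by phase.
"""

import json
from pathlib import Path

import numpy as np

from habitatpipe import pipeline as pl
from habitatpipe import preprocess as pp

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = pl.PipelineConfig.from_json(RESULTS / "config.json")
    pl.run_stage("preprocess", config)
    ref = pp.ReferenceHistogram.from_json(
        Path(config.out_dir) / "preprocess" / "reference_histogram.json"
    )
    for phase, vals in ref.values.items():
        print(
            f"reference {phase}: ROI intensity range "
            f"[{vals[0]:.0f}, {vals[-1]:.0f}], median {np.median(vals):.0f}"
        )
    print("validation cohort matched to the development reference")


if __name__ == "__main__":
    main()
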