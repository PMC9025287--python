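"""Discover the perfusion habitats by population-level clustering.

Pools the quantised perfusion feature vectors of all development
patients, sweeps k-means over the configured k range with repeated
restarts, selects the habitat count from the averaged Calinski-Harabasz
and silhouette curves, and propagates the frozen centres to the
validation cohort.  Writes the habitat model, selection diagnostics and
per-patient habitat label maps.
"""

from pathlib import Path

import pandas as pd

from habitatpipe import habitats as hb
from habitatpipe import pipeline as pl

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = pl.PipelineConfig.from_json(RESULTS / "config.json")
    pl.run_stage("habitats", config)
    out = Path(config.out_dir) / "habitats"
    model = hb.HabitatModel.from_json(out / "habitat_model.json")
    print(f"selected k = {model.k} habitats")
    print("centres (wash-in, washout, washout ratio), canonical order:")
    for i, c in enumerate(model.centers, 1):
        print(f"  habitat {i}: ({c[0]:8.1f}, {c[1]:8.1f}, {c[2]:6.3f})")
    for cohort in ("development", "validation"):
        props = pd.read_csv(out / cohort / "habitat_proportions.csv")
        mean_props = props.drop(columns="pid").mean()
        print(f"{cohort} mean habitat proportions:")
        print("  " + ", ".join(f"{v:.3f}" for v in mean_props))


if __name__ == "__main__":
    main()
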