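"""Quantify spatial heterogeneity of each habitat map.

Extracts the 58-feature panel (4 histogram + 24 GLCM + 16 GLSZM features
of the habitat label map, 14 shape features of the ROI) plus per-habitat
volume proportions for every patient, and the whole-tumour comparator
panels (24 GLCM features per phase image and per perfusion map).
"""

from pathlib import Path

import pandas as pd

from habitatpipe import pipeline as pl

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = pl.PipelineConfig.from_json(RESULTS / "config.json")
    pl.run_stage("features", config)
    out = Path(config.out_dir) / "features"
    hab = pd.read_csv(out / "development_habitat_features.csv")
    dce = pd.read_csv(out / "development_dce_features.csv")
    per = pd.read_csv(out / "development_perfusion_features.csv")
    n_prop = sum(c.startswith("prop_") for c in hab.columns)
    print(
        f"habitat panel: {hab.shape[1] - 1 - n_prop} heterogeneity features "
        f"+ {n_prop} proportions x {len(hab)} patients"
    )
    print(f"whole-tumour DCE panel: {dce.shape[1] - 1} features")
    print(f"whole-tumour perfusion panel: {per.shape[1] - 1} features")


if __name__ == "__main__":
    main()
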