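"""Derive the voxelwise perfusion maps for every patient.

Computes wash-in (early minus pre-contrast), washout (early minus
delayed) and the washout ratio (zero when the curve keeps rising) inside
each tumour ROI, and writes them as NIfTI volumes.
"""

from pathlib import Path

import numpy as np

from habitatpipe import pipeline as pl

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = pl.PipelineConfig.from_json(RESULTS / "config.json")
    pl.run_stage("perfusion", config)
    maps = pl._load_maps(config, "development")
    pool = np.concatenate([m.pfv() for m in maps])
    print(f"development cohort: {len(pool)} tumour voxels pooled")
    for name, col in zip(("wash-in", "washout", "washout ratio"), pool.T):
        print(
            f"  {name}: mean {col.mean():.1f}, "
            f"5-95% [{np.percentile(col, 5):.1f}, {np.percentile(col, 95):.1f}]"
        )


if __name__ == "__main__":
    main()
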