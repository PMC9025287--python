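"""Stage-wise orchestration of the habitat analysis.

Stages (``simulate``, ``preprocess``, ``perfusion``, ``habitats``,
``features``, ``fit``, ``evaluate``) communicate through artifacts on
disk (NIfTI volumes, CSV tables, JSON models) so each is independently
testable, resumable and idempotent under a fixed seed.  Every stage
writes the resolved configuration and its hash next to its outputs.

Command line::

    habitatpipe <stage> --config config.json [--seed N] [--out DIR]
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import nibabel as nib
import numpy as np
import pandas as pd

from habitatpipe import cohort as co
from habitatpipe import features as ft
from habitatpipe import habitats as hb
from habitatpipe import perfusion as pf
from habitatpipe import preprocess as pp
from habitatpipe import survival as sv

log = logging.getLogger("habitatpipe")

STAGES = ("simulate", "preprocess", "perfusion", "habitats", "features", "fit", "evaluate")
COHORTS = ("development", "validation")

__all__ = ["PipelineConfig", "run_stage", "run_all", "main", "STAGES"]


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    n_dev: int = 308
    n_val: int = 147
    volume_shape: tuple[int, int, int] = (64, 64, 20)
    tumor_radius_range: tuple[float, float] = (6.0, 14.0)
    k_min: int = 2
    k_max: int = 32
    n_reps: int = 100
    n_bins: int = 256
    silhouette_sample: int = 2048
    whole_tumor_bins: int = 32
    n_boot: int = 200
    baseline_hazard: float = 0.0013
    censor_time: float = 108.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        for key in ("volume_shape", "tumor_radius_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_dir(config: PipelineConfig, stage: str, create: bool = False) -> Path:
    d = Path(config.out_dir) / stage
    if create:
        d.mkdir(parents=True, exist_ok=True)
    return d


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run stage {producing_stage!r} first"
        )
    return path


def _finish(config: PipelineConfig, stage: str) -> None:
    d = _stage_dir(config, stage, create=True)
    (d / "stage.json").write_text(
        json.dumps({"stage": stage, "seed": config.seed, "config_hash": config.config_hash})
    )
    config.to_json(d / "config.json")
    log.info("stage %s complete (config %s)", stage, config.config_hash)


def _cohort_specs(config: PipelineConfig) -> dict[str, co.CohortSpec]:
    common = dict(
        volume_shape=config.volume_shape,
        tumor_radius_range=config.tumor_radius_range,
        baseline_hazard=config.baseline_hazard,
        censor_time=config.censor_time,
    )
    return {
        "development": co.development_spec(
            n_patients=config.n_dev, seed=config.seed, **common
        ),
        "validation": co.validation_spec(
            n_patients=config.n_val, seed=config.seed + 1, **common
        ),
    }


def _pids(config: PipelineConfig, cohort: str) -> list[str]:
    manifest = json.loads(
        _require(
            _stage_dir(config, "simulate") / cohort / "manifest.json", "simulate"
        ).read_text()
    )
    return [e["pid"] for e in manifest["patients"]]


def _load_maps(config: PipelineConfig, cohort: str) -> list[pf.PerfusionMaps]:
    d = _require(_stage_dir(config, "perfusion") / cohort, "perfusion")
    maps = []
    for pid in _pids(config, cohort):
        vols = {}
        spacing = None
        for name in ("ein", "eout", "rwo", "roi"):
            img = nib.load(d / f"{pid}_{name}.nii.gz")
            vols[name] = np.asarray(img.dataobj, dtype=float)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        maps.append(
            pf.PerfusionMaps(
                pid=pid,
                ein=vols["ein"],
                eout=vols["eout"],
                rwo=vols["rwo"],
                roi=vols["roi"] > 0.5,
                spacing=spacing,
            )
        )
    return maps


# ---------------------------------------------------------------------------
# stage implementations

def _stage_simulate(config: PipelineConfig) -> None:
    for cohort, spec in _cohort_specs(config).items():
        patients = co.generate_cohort(spec)
        co.write_cohort(patients, _stage_dir(config, "simulate", True) / cohort, spec)


def _stage_preprocess(config: PipelineConfig) -> None:
    out = _stage_dir(config, "preprocess", True)
    resampled: dict[str, list[pp.DCEStudy]] = {}
    for cohort in COHORTS:
        src = _require(_stage_dir(config, "simulate") / cohort, "simulate")
        studies = []
        for pid in _pids(config, cohort):
            study = pp.load_study(src, pid, cohort=cohort)
            studies.append(pp.resample_isotropic(study))
        resampled[cohort] = studies
    reference = pp.build_reference_histogram(resampled["development"], config.n_bins)
    reference.to_json(out / "reference_histogram.json")
    for cohort, studies in resampled.items():
        d = out / cohort
        for study in studies:
            if cohort == "validation":
                study = pp.histogram_match(study, reference)
            pp.save_study(study, d)


def _stage_perfusion(config: PipelineConfig) -> None:
    out = _stage_dir(config, "perfusion", True)
    for cohort in COHORTS:
        src = _require(_stage_dir(config, "preprocess") / cohort, "preprocess")
        d = out / cohort
        d.mkdir(parents=True, exist_ok=True)
        for pid in _pids(config, cohort):
            study = pp.load_study(src, pid, cohort=cohort)
            maps = pf.compute_perfusion_maps(study)
            pf.save_maps(maps, d)
            affine = np.diag(list(maps.spacing) + [1.0])
            nib.save(
                nib.Nifti1Image(maps.roi.astype(np.uint8), affine),
                d / f"{pid}_roi.nii.gz",
            )


def _stage_habitats(config: PipelineConfig) -> None:
    out = _stage_dir(config, "habitats", True)
    dev_maps = _load_maps(config, "development")
    pool = np.concatenate([m.pfv() for m in dev_maps])
    quantizer = hb.fit_quantizer(pool, n_bins=config.n_bins)
    table = hb.build_pfv_table(dev_maps, quantizer)
    models, diag = hb.sweep_k(
        table,
        k_range=range(config.k_min, config.k_max + 1),
        n_reps=config.n_reps,
        seed=config.seed,
        quantizer=quantizer,
        silhouette_sample=config.silhouette_sample,
    )
    diag.to_csv(out / "selection_diagnostics.csv", index=False)
    k_star = hb.select_k(diag)
    model = models[k_star]
    model.diagnostics = diag
    model.to_json(out / "habitat_model.json")
    log.info("selected k = %d habitats", k_star)

    for cohort in COHORTS:
        d = out / cohort
        d.mkdir(parents=True, exist_ok=True)
        rows = []
        for maps in (dev_maps if cohort == "development" else _load_maps(config, cohort)):
            hmap = hb.build_habitat_map(maps, model)
            affine = np.diag(list(maps.spacing) + [1.0])
            nib.save(
                nib.Nifti1Image(hmap.labels.astype(np.int16), affine),
                d / f"{maps.pid}_habitats.nii.gz",
            )
            rows.append({"pid": maps.pid, **{
                f"prop_habitat_{i+1}": p for i, p in enumerate(hmap.proportions)
            }})
        pd.DataFrame(rows).to_csv(d / "habitat_proportions.csv", index=False)


def _stage_features(config: PipelineConfig) -> None:
    out = _stage_dir(config, "features", True)
    model = hb.HabitatModel.from_json(
        _require(_stage_dir(config, "habitats") / "habitat_model.json", "habitats")
    )
    for cohort in COHORTS:
        hab_dir = _require(_stage_dir(config, "habitats") / cohort, "habitats")
        img_dir = _require(_stage_dir(config, "preprocess") / cohort, "preprocess")
        per_dir = _require(_stage_dir(config, "perfusion") / cohort, "perfusion")
        hab_rows, dce_rows, perf_rows = [], [], []
        for pid in _pids(config, cohort):
            img = nib.load(hab_dir / f"{pid}_habitats.nii.gz")
            labels = np.asarray(img.dataobj).astype(np.int16)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            hab_rows.append(
                {"pid": pid, **ft.extract_habitat_features(labels, spacing, model.k)}
            )
            study = pp.load_study(img_dir, pid, cohort=cohort)
            row = {"pid": pid}
            for name in pp.PHASES:
                row.update(
                    ft.whole_tumor_features(
                        getattr(study, name), study.roi,
                        n_bins=config.whole_tumor_bins, prefix=f"{name}_",
                    )
                )
            dce_rows.append(row)
            row = {"pid": pid}
            for name in ("ein", "eout", "rwo"):
                vol = np.asarray(
                    nib.load(per_dir / f"{pid}_{name}.nii.gz").dataobj, dtype=float
                )
                row.update(
                    ft.whole_tumor_features(
                        vol, study.roi,
                        n_bins=config.whole_tumor_bins, prefix=f"{name}_",
                    )
                )
            perf_rows.append(row)
        pd.DataFrame(hab_rows).to_csv(out / f"{cohort}_habitat_features.csv", index=False)
        pd.DataFrame(dce_rows).to_csv(out / f"{cohort}_dce_features.csv", index=False)
        pd.DataFrame(perf_rows).to_csv(out / f"{cohort}_perfusion_features.csv", index=False)


def _cohort_tables(config: PipelineConfig, cohort: str) -> dict:
    fdir = _require(_stage_dir(config, "features"), "features")
    clin = pd.read_csv(
        _require(_stage_dir(config, "simulate") / cohort / "clinical.csv", "simulate")
    )
    tables = {"time": clin["time_months"].to_numpy(), "event": clin["event"].to_numpy()}
    for key in ("habitat", "dce", "perfusion"):
        df = pd.read_csv(fdir / f"{cohort}_{key}_features.csv")
        tables[f"{key}_features"] = df.drop(columns=["pid"])
    drop = ["pid", "time_months", "event", "true_linear_predictor", "age"]
    clin_x = clin.drop(columns=[c for c in drop if c in clin.columns])
    clin_x.insert(0, "age", clin["age"])
    tables["clinical"] = clin_x
    return tables


def _stage_fit(config: PipelineConfig) -> None:
    out = _stage_dir(config, "fit", True)
    dev = _cohort_tables(config, "development")
    dev_z, stats = ft.z_score_normalize(dev["habitat_features"])
    model = sv.fit_cox_lasso(
        dev_z, dev["time"], dev["event"], seed=config.seed, zscore_stats=stats
    )
    model.to_json(out / "hrs_model.json")
    rows = []
    for cohort in COHORTS:
        tables = dev if cohort == "development" else _cohort_tables(config, cohort)
        z, _ = ft.z_score_normalize(tables["habitat_features"], stats)
        scores = sv.compute_risk_score(model, z)
        for pid, s in zip(_pids(config, cohort), scores):
            rows.append({"pid": pid, "cohort": cohort, "hrs": s,
                         "high_risk": bool(s >= model.cutoff)})
    pd.DataFrame(rows).to_csv(out / "habitat_risk_scores.csv", index=False)


def _stage_evaluate(config: PipelineConfig) -> None:
    out = _stage_dir(config, "evaluate", True)
    _require(_stage_dir(config, "fit") / "hrs_model.json", "fit")
    dev = _cohort_tables(config, "development")
    val = _cohort_tables(config, "validation")
    report, models = sv.build_all_risk_models(
        dev, val, seed=config.seed, n_boot=config.n_boot
    )
    report.to_csv(out / "risk_model_report.csv", index=False)
    cutoff_rows = [
        {"model": name, "cutoff": m.cutoff, "lambda": m.lambda_, "h0": m.h0,
         "n_selected": len(m.feature_names)}
        for name, m in models.items()
    ]
    pd.DataFrame(cutoff_rows).to_csv(out / "model_cutoffs.csv", index=False)
    for name, m in models.items():
        m.to_json(out / f"model_{name}.json")


_IMPL = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "perfusion": _stage_perfusion,
    "habitats": _stage_habitats,
    "features": _stage_features,
    "fit": _stage_fit,
    "evaluate": _stage_evaluate,
}


def run_stage(stage: str, config: PipelineConfig) -> Path:
    """Run one pipeline stage; returns the stage output directory."""
    if stage not in _IMPL:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    _IMPL[stage](config)
    _finish(config, stage)
    return _stage_dir(config, stage)


def run_all(config: PipelineConfig) -> Path:
    for stage in STAGES:
        run_stage(stage, config)
    return Path(config.out_dir)


@click.command()
@click.argument("stage", type=click.Choice(STAGES + ("all",)))
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_dir", type=click.Path(), default=None)
def main(stage: str, config_path: str | None, seed: int | None, out_dir: str | None):
    """Run one stage (or `all`) of the perfusion-habitat pipeline."""
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    config = PipelineConfig.from_json(config_path) if config_path else PipelineConfig()
    if seed is not None:
        config.seed = seed
    if out_dir is not None:
        config.out_dir = out_dir
    if stage == "all":
        run_all(config)
    else:
        run_stage(stage, config)


if __name__ == "__main__":
    main()
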