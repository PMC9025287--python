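"""Synthetic dual-cohort DCE-MRI generator with planted perfusion habitats.

Real breast DCE-MRI cohorts with linked survival outcomes cannot be
redistributed, so this module generates studies carrying the exact
statistical structure the analysis assumes: each tumour voxel belongs to
one of k perfusion habitats with known (wash-in, washout-ratio) kinetic
centres and mixing proportions, phases are rendered by inverting the
perfusion-map definitions, and disease-free survival times follow an
exponential-baseline Cox model on habitat-heterogeneity features plus
clinicopathological covariates.

Two generation modes exist:

* ``sample_pfvs`` emits bare perfusion-feature-vector tables drawn
  around the habitat centres — exact centre control for clustering
  tests;
* ``generate_cohort`` renders full volumes (pre/early/delayed phases +
  ROI mask) for end-to-end pipeline runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from habitatpipe.preprocess import DCEStudy, save_study, load_study

__all__ = [
    "HABITAT_CENTERS",
    "HABITAT_PROPORTIONS",
    "CohortSpec",
    "SyntheticPatient",
    "development_spec",
    "validation_spec",
    "sample_pfvs",
    "generate_tumor_mask",
    "assign_habitats",
    "render_dce",
    "simulate_clinical",
    "simulate_survival",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

# Reference kinetic centres of the five perfusion habitats: rows are
# (wash-in, washout, washout ratio) in development-cohort intensity
# units.  Habitat 1 is the low-enhancement persistent habitat; 2 and 3
# enhance strongly (washout vs. plateau); 4 and 5 show washout kinetics.
HABITAT_CENTERS = np.array(
    [
        [825.0, -667.0, 0.021],
        [2420.0, 864.0, 0.361],
        [2206.0, -14.0, 0.075],
        [1154.0, 362.0, 0.338],
        [1302.0, 915.0, 0.717],
    ]
)

# Voxel fraction of each habitat across the development cohort.
HABITAT_PROPORTIONS = np.array([0.419, 0.068, 0.256, 0.235, 0.022])

# Per-feature PFV noise SD, roughly 2.5% of each feature's dynamic
# range.  The habitats are planted as distinct kinetic subpopulations,
# not a continuum, so the within-habitat spread must stay small against
# the tightest inter-centre separation (habitats 4 vs 5, ~570 intensity
# units in the wash-in/washout plane).
DEFAULT_PFV_NOISE = np.array([50.0, 50.0, 0.025])

# Marginal frequencies of the clinicopathological covariates in the
# development cohort (counts / 308).
_CLINICAL_MARGINALS = {
    "t_stage": ([1, 2, 3, 4], [187, 112, 7, 2]),
    "n_stage": ([0, 1, 2, 3], [189, 98, 14, 7]),
    "grade": ([1, 2, 3], [82, 153, 73]),
    "lvi_positive": ([1, 0], [90, 218]),
    "eic_positive": ([1, 0], [81, 227]),
    "er_negative": ([1, 0], [64, 244]),
    "pr_negative": ([1, 0], [90, 218]),
    "her2_positive": ([1, 0], [59, 249]),
    "p53_positive": ([1, 0], [96, 212]),
    "ki67_high": ([1, 0], [144, 164]),
    "adj_chemo": ([1, 0], [198, 110]),
    "adj_rt": ([1, 0], [241, 67]),
    "adj_endocrine": ([1, 0], [245, 63]),
    "shape_irregular": ([1, 0], [259, 49]),
    "margin_not_circumscribed": ([1, 0], [291, 17]),
    "enhancement_rim": ([1, 0], [77, 231]),
    "enhancement_heterogeneous": ([1, 0], [203, 105]),
}

# Planted log-hazard contributions of clinical covariates (clinical-model
# coefficient scale); habitat-feature coefficients are planted on the
# z-scored heterogeneity features of the ground-truth habitat map.
DEFAULT_CLINICAL_BETA = {
    "n_stage": 0.199,
    "lvi_positive": 0.624,
    "er_negative": 0.398,
    "pr_negative": 0.325,
    "ki67_high": 0.623,
}
# Planted on heterogeneity features that are stable across acquisition
# grids (label-histogram entropy, normalised co-occurrence homogeneity,
# surface-to-volume): zone-size statistics are not comparable between
# the anisotropic acquisition grid and the resampled 1 mm grid, so a
# hazard planted on them could not be recovered from images even in
# principle.
DEFAULT_FEATURE_BETA = {
    "hist_Entropy": 0.6,
    "glcm_Idmn": -0.8,
    "shape_SurfaceVolumeRatio": -0.4,
}


@dataclass
class CohortSpec:
    """Generation parameters for one synthetic cohort."""

    name: str = "development"
    n_patients: int = 308
    voxel_spacing: tuple[float, float, float] = (0.85, 0.85, 3.0)
    volume_shape: tuple[int, int, int] = (64, 64, 20)
    tumor_radius_range: tuple[float, float] = (6.0, 14.0)  # mm
    habitat_ein: np.ndarray = field(
        default_factory=lambda: HABITAT_CENTERS[:, 0].copy()
    )
    habitat_rwo: np.ndarray = field(
        default_factory=lambda: HABITAT_CENTERS[:, 2].copy()
    )
    habitat_proportions: np.ndarray = field(
        default_factory=lambda: HABITAT_PROPORTIONS.copy()
    )
    # habitat patch correlation length (voxels); patches must span several
    # slices (~1 cm at 3 mm spacing) to survive 1 mm resampling, matching
    # the large contiguous subregions visible in real habitat maps
    spatial_clump: float = 4.0
    # the analysis ROI excludes the tumour rim (clinical ROIs avoid edge
    # voxels to dodge partial-volume effects); 0 disables erosion
    roi_margin_voxels: int = 1
    noise_sd: np.ndarray = field(default_factory=lambda: DEFAULT_PFV_NOISE.copy())
    image_noise_sd: float = 30.0  # additive phase noise, intensity units
    baseline_intensity: float = 400.0
    # strictly monotone validation-scanner map f(x) = a * x**gamma + b;
    # identity for the development cohort
    scanner_transform: tuple[float, float, float] = (1.0, 1.0, 0.0)
    feature_beta: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_BETA)
    )
    clinical_beta: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_BETA)
    )
    baseline_hazard: float = 0.0013  # events / month
    censor_time: float = 108.0  # administrative censoring, months
    seed: int = 0

    def __post_init__(self) -> None:
        self.habitat_ein = np.asarray(self.habitat_ein, dtype=float)
        self.habitat_rwo = np.asarray(self.habitat_rwo, dtype=float)
        self.habitat_proportions = np.asarray(self.habitat_proportions, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if not (
            len(self.habitat_ein)
            == len(self.habitat_rwo)
            == len(self.habitat_proportions)
        ):
            raise ValueError("habitat centre and proportion lengths differ")
        if abs(self.habitat_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("habitat proportions must sum to 1")
        if np.any(self.habitat_proportions < 0):
            raise ValueError("habitat proportions must be non-negative")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")

    @property
    def n_habitats(self) -> int:
        return len(self.habitat_proportions)

    def to_json(self, path: str | Path) -> None:
        d = {
            k: (v.tolist() if isinstance(v, np.ndarray) else
                dict(v) if isinstance(v, Mapping) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        d = json.loads(Path(path).read_text())
        for key in ("voxel_spacing", "volume_shape", "tumor_radius_range",
                    "scanner_transform"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def development_spec(**overrides) -> CohortSpec:
    return CohortSpec(name="development", **overrides)


def validation_spec(**overrides) -> CohortSpec:
    """Validation cohort: different scanner, spacing and case mix knobs."""
    defaults = dict(
        name="validation",
        n_patients=147,
        voxel_spacing=(0.8, 0.8, 3.0),
        scanner_transform=(1.35, 0.93, 150.0),
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


@dataclass
class SyntheticPatient:
    """One generated patient with its ground truth."""

    study: DCEStudy
    true_habitat_map: np.ndarray
    clinical: dict
    true_linear_predictor: float
    survival_time: float
    event: int


# ---------------------------------------------------------------------------
# pfv mode

def sample_pfvs(
    n_voxels: int,
    seed: int,
    centers: np.ndarray | None = None,
    proportions: np.ndarray | None = None,
    noise_sd: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a bare PFV table around the habitat centres.

    Returns ``(pfvs, labels)`` where ``pfvs`` is (n, 3) with columns
    (wash-in, washout, washout ratio) and ``labels`` are 1-based habitat
    indices.  Values are Gaussian around the centre triplets and left
    unclipped: this mode feeds clustering unit tests that need exact
    centre control, not image rendering.
    """
    centers = HABITAT_CENTERS if centers is None else np.asarray(centers, float)
    proportions = (
        HABITAT_PROPORTIONS if proportions is None else np.asarray(proportions, float)
    )
    noise_sd = DEFAULT_PFV_NOISE if noise_sd is None else np.asarray(noise_sd, float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(proportions), size=n_voxels, p=proportions) + 1
    pfvs = centers[labels - 1] + rng.standard_normal((n_voxels, 3)) * noise_sd
    return pfvs, labels


# ---------------------------------------------------------------------------
# image mode

def generate_tumor_mask(
    spec: CohortSpec, seed: int, radius_mm: float | None = None
) -> np.ndarray:
    """Rasterise a spherical tumour at a random interior position.

    The sphere is defined in physical millimetres, so anisotropic voxel
    spacing yields an anisotropic voxel footprint.  Raises if the
    requested radius cannot fit inside the field of view.
    """
    rng = np.random.default_rng(seed)
    if radius_mm is None:
        radius_mm = rng.uniform(*spec.tumor_radius_range)
    shape = spec.volume_shape
    spacing = np.asarray(spec.voxel_spacing)
    extent = (np.asarray(shape) - 1) * spacing
    if np.any(2 * radius_mm > extent):
        raise ValueError(
            f"tumour radius {radius_mm} mm does not fit field of view {extent} mm"
        )
    lo = radius_mm / spacing
    hi = (np.asarray(shape) - 1) - radius_mm / spacing
    center = np.array([rng.uniform(l, h) for l, h in zip(lo, hi)])
    grid = np.indices(shape, dtype=float)
    d2 = sum(
        ((grid[a] - center[a]) * spacing[a]) ** 2 for a in range(3)
    )
    mask = d2 <= radius_mm**2
    if not mask.any():  # degenerate sub-voxel radius: keep the centre voxel
        mask[tuple(np.round(center).astype(int))] = True
    return mask


def assign_habitats(
    mask: np.ndarray,
    proportions: np.ndarray,
    spatial_clump: float,
    seed: int,
) -> np.ndarray:
    """Partition ROI voxels into habitats at the target proportions.

    With ``spatial_clump == 0`` labels are i.i.d. multinomial.  With a
    positive clump length, Gaussian-smoothed white noise is
    rank-transformed to uniforms inside the mask and thresholded at the
    cumulative proportions, which produces spatially contiguous patches
    whose empirical proportions match the targets to within one voxel.
    """
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9 or np.any(proportions < 0):
        raise ValueError("proportions must be non-negative and sum to 1")
    if not mask.any():
        raise ValueError("mask is empty")
    rng = np.random.default_rng(seed)
    k = len(proportions)
    labels = np.zeros(mask.shape, dtype=np.int16)
    n = int(mask.sum())
    if spatial_clump <= 0:
        labels[mask] = rng.choice(k, size=n, p=proportions) + 1
        return labels
    noise = rng.standard_normal(mask.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=spatial_clump)
    u = np.empty(n)
    u[np.argsort(smooth[mask], kind="stable")] = (np.arange(n) + 0.5) / n
    edges = np.cumsum(proportions)
    labels[mask] = np.searchsorted(edges, u, side="left") + 1
    labels[mask] = np.minimum(labels[mask], k)
    return labels


def _apply_scanner(volume: np.ndarray, transform: tuple[float, float, float]) -> np.ndarray:
    a, gamma, b = transform
    if a <= 0 or gamma <= 0:
        raise ValueError("scanner transform must be strictly monotone (a, gamma > 0)")
    return a * np.power(np.clip(volume, 0.0, None), gamma) + b


def render_dce(
    labels: np.ndarray, spec: CohortSpec, seed: int, pid: str = "p000"
) -> DCEStudy:
    """Render pre/early/delayed phases from a planted habitat label map.

    Tumour voxels invert the perfusion-map definitions: the early phase
    adds the habitat's wash-in to the pre-contrast baseline, and the
    delayed phase applies the habitat's washout ratio to the early
    signal.  Background voxels get low-enhancement persistent texture.
    All intensities are clipped at zero, and the validation scanner's
    monotone intensity map is applied last.
    """
    k = spec.n_habitats
    if labels.max() > k or labels.min() < 0:
        raise ValueError("label map inconsistent with spec habitats")
    rng = np.random.default_rng(seed)
    shape = labels.shape
    mask = labels > 0
    sd = spec.image_noise_sd

    pre = np.full(shape, spec.baseline_intensity) + sd * rng.standard_normal(shape)
    # background: gentle persistent enhancement so histogram matching has
    # realistic low-intensity support
    bg_ein = np.abs(rng.normal(60.0, 40.0, size=shape))
    ein_field = np.where(mask, spec.habitat_ein[np.maximum(labels, 1) - 1], bg_ein)
    rwo_field = np.where(mask, spec.habitat_rwo[np.maximum(labels, 1) - 1], 0.0)
    early = pre + ein_field + sd * rng.standard_normal(shape)
    delayed = early * (1.0 - rwo_field) + sd * rng.standard_normal(shape)

    pre, early, delayed = (np.clip(v, 0.0, None) for v in (pre, early, delayed))
    pre = _apply_scanner(pre, spec.scanner_transform)
    early = _apply_scanner(early, spec.scanner_transform)
    delayed = _apply_scanner(delayed, spec.scanner_transform)
    return DCEStudy(
        pid=pid,
        pre=pre,
        early=early,
        delayed=delayed,
        roi=mask,
        spacing=spec.voxel_spacing,
        cohort=spec.name,
    )


# ---------------------------------------------------------------------------
# outcomes

def simulate_clinical(rng: np.random.Generator) -> dict:
    """Draw one patient's clinicopathological/radiological covariates."""
    rec = {"age": float(np.round(rng.normal(51.2, 10.5), 1))}
    for name, (values, counts) in _CLINICAL_MARGINALS.items():
        p = np.asarray(counts, dtype=float)
        rec[name] = int(rng.choice(values, p=p / p.sum()))
    return rec


def simulate_survival(
    linear_predictor: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Exponential-baseline Cox survival with administrative censoring.

    ``T = -log(U) / (h_base * exp(LP))``; the observation is censored at
    ``spec.censor_time`` months.
    """
    if spec.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    u = rng.uniform()
    t = -np.log(u) / (spec.baseline_hazard * np.exp(linear_predictor))
    if t <= spec.censor_time:
        return float(max(t, 1e-6)), 1
    return float(spec.censor_time), 0


def _heterogeneity_features(labels: np.ndarray, spacing, k: int) -> dict[str, float]:
    # local import: features module is independent of the generator
    from habitatpipe import features as ft

    mask = labels > 0
    out = {}
    out.update(ft.glcm_features(labels, n_levels=k))
    out.update(ft.glszm_features(labels, n_levels=k))
    out.update(ft.histogram_features(labels))
    out.update(ft.shape_features(mask, spacing))
    return out


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> list[SyntheticPatient]:
    """Generate a full image-mode cohort with linked survival outcomes.

    Per-patient volumes are rendered first; the planted linear predictor
    combines the cohort-z-scored heterogeneity features of the
    ground-truth habitat map (weighted by ``spec.feature_beta``) with
    centred clinical covariates (weighted by ``spec.clinical_beta``).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    patients: list[SyntheticPatient] = []
    feat_rows = []
    for i in range(spec.n_patients):
        pid = f"{spec.name[:3]}{i:03d}"
        sub = int(rng.integers(0, 2**31 - 1))
        mask = generate_tumor_mask(spec, seed=sub)
        labels = assign_habitats(
            mask, spec.habitat_proportions, spec.spatial_clump, seed=sub + 1
        )
        study = render_dce(labels, spec, seed=sub + 2, pid=pid)
        if spec.roi_margin_voxels > 0:
            eroded = ndimage.binary_erosion(
                mask, iterations=spec.roi_margin_voxels
            )
            if eroded.sum() >= 20:  # keep tiny tumours un-eroded
                study = dataclasses.replace(study, roi=eroded)
                labels = np.where(eroded, labels, 0).astype(labels.dtype)
        clinical = simulate_clinical(rng)
        patients.append(
            SyntheticPatient(
                study=study,
                true_habitat_map=labels,
                clinical=clinical,
                true_linear_predictor=0.0,
                survival_time=0.0,
                event=0,
            )
        )
        feat_rows.append(
            _heterogeneity_features(labels, spec.voxel_spacing, spec.n_habitats)
        )
    feats = pd.DataFrame(feat_rows)
    sd = feats.std(ddof=0).replace(0.0, 1.0)
    z = (feats - feats.mean()) / sd
    for i, patient in enumerate(patients):
        lp = 0.0
        for name, beta in spec.feature_beta.items():
            if name not in z.columns:
                raise KeyError(f"planted coefficient on unknown feature {name!r}")
            lp += beta * float(z.loc[i, name])
        for name, beta in spec.clinical_beta.items():
            x = patient.clinical[name]
            # centre ordinal/binary covariates so the baseline hazard keeps
            # its interpretation for an average patient
            values, counts = _CLINICAL_MARGINALS[name]
            p = np.asarray(counts, float) / sum(counts)
            lp += beta * (x - float(np.dot(values, p)))
        time, event = simulate_survival(lp, spec, rng)
        patient.true_linear_predictor = lp
        patient.survival_time = time
        patient.event = event
    return patients


# ---------------------------------------------------------------------------
# disk round-trip

def write_cohort(
    patients: Sequence[SyntheticPatient], directory: str | Path, spec: CohortSpec
) -> dict:
    """Write NIfTI volumes, the clinical CSV and a manifest; return the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    import nibabel as nib

    rows = []
    entries = []
    for patient in patients:
        paths = save_study(patient.study, directory)
        affine = np.diag(list(patient.study.spacing) + [1.0])
        th = directory / f"{patient.study.pid}_true_habitats.nii.gz"
        nib.save(nib.Nifti1Image(patient.true_habitat_map.astype(np.int16), affine), th)
        paths["true_habitats"] = str(th)
        entries.append({"pid": patient.study.pid, "paths": paths})
        rows.append(
            {
                "pid": patient.study.pid,
                "time_months": patient.survival_time,
                "event": patient.event,
                "true_linear_predictor": patient.true_linear_predictor,
                **patient.clinical,
            }
        )
    clinical = pd.DataFrame(rows)
    csv_path = directory / "clinical.csv"
    clinical.to_csv(csv_path, index=False)
    spec_path = directory / "cohort_spec.json"
    spec.to_json(spec_path)
    manifest = {
        "cohort": spec.name,
        "n_patients": len(patients),
        "seed": spec.seed,
        "clinical_csv": str(csv_path),
        "spec_json": str(spec_path),
        "patients": entries,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_cohort(directory: str | Path) -> tuple[list[SyntheticPatient], pd.DataFrame, CohortSpec]:
    """Load a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = CohortSpec.from_json(manifest["spec_json"])
    clinical = pd.read_csv(manifest["clinical_csv"])
    import nibabel as nib

    patients = []
    for entry, (_, row) in zip(manifest["patients"], clinical.iterrows()):
        pid = entry["pid"]
        study = load_study(directory, pid, cohort=manifest["cohort"])
        labels = np.asarray(
            nib.load(entry["paths"]["true_habitats"]).dataobj
        ).astype(np.int16)
        clin = {
            c: row[c]
            for c in clinical.columns
            if c not in ("pid", "time_months", "event", "true_linear_predictor")
        }
        patients.append(
            SyntheticPatient(
                study=study,
                true_habitat_map=labels,
                clinical=clin,
                true_linear_predictor=float(row["true_linear_predictor"]),
                survival_time=float(row["time_months"]),
                event=int(row["event"]),
            )
        )
    return patients, clinical, spec
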