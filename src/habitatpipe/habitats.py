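"""Population-level discovery of perfusion habitats.

Voxel perfusion feature vectors (PFVs) from every development-cohort
patient are pooled, each feature is quantised onto a 256-bin grid
spanning its pooled range, and k-means (Euclidean distance, k-means++
initialisation, Lloyd iterations) is run at the cohort level for k from
2 to 32.  Candidate k values are scored by the Calinski-Harabasz index
and the silhouette coefficient averaged over repeated restarts, and the
chosen model's centres are frozen and propagated verbatim to the
validation cohort, whose voxels are labelled by nearest centre.

Clustering operates in raw quantised units (no per-feature
standardisation): habitat centres are then directly interpretable as
intensity-unit kinetics.  A ``standardize`` flag exists for sensitivity
analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from habitatpipe.perfusion import PerfusionMaps

__all__ = [
    "QuantizerModel",
    "PFVTable",
    "HabitatModel",
    "HabitatMap",
    "fit_quantizer",
    "build_pfv_table",
    "population_kmeans",
    "score_partition",
    "sweep_k",
    "select_k",
    "build_habitat_map",
    "match_centers",
]

FEATURE_NAMES = ("ein", "eout", "rwo")


@dataclass
class QuantizerModel:
    """Per-feature uniform 256-bin quantiser fitted on the development pool."""

    minima: np.ndarray
    maxima: np.ndarray
    n_bins: int = 256

    def __post_init__(self) -> None:
        self.minima = np.asarray(self.minima, dtype=float)
        self.maxima = np.asarray(self.maxima, dtype=float)

    @property
    def bin_width(self) -> np.ndarray:
        return (self.maxima - self.minima) / self.n_bins

    def bin_centers(self, feature: int) -> np.ndarray:
        w = self.bin_width[feature]
        if w == 0:
            return np.array([self.minima[feature]])
        return self.minima[feature] + (np.arange(self.n_bins) + 0.5) * w

    def quantize(self, values: np.ndarray) -> np.ndarray:
        """Map raw (n, f) values to the centres of their bins.

        Bins are left-closed with a right-closed last bin, so the pooled
        maximum falls in bin 255; out-of-range values (validation cohort
        quantised with the development grid) clip to the edge bins.
        """
        values = np.atleast_2d(np.asarray(values, dtype=float))
        out = np.empty_like(values)
        for f in range(values.shape[1]):
            w = self.bin_width[f]
            if w == 0:
                out[:, f] = self.minima[f]
                continue
            idx = np.floor((values[:, f] - self.minima[f]) / w).astype(int)
            idx = np.clip(idx, 0, self.n_bins - 1)
            out[:, f] = self.minima[f] + (idx + 0.5) * w
        return out

    def to_dict(self) -> dict:
        return {
            "minima": self.minima.tolist(),
            "maxima": self.maxima.tolist(),
            "n_bins": self.n_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuantizerModel":
        return cls(np.asarray(d["minima"]), np.asarray(d["maxima"]), int(d["n_bins"]))


def fit_quantizer(pfv_pool: np.ndarray, n_bins: int = 256) -> QuantizerModel:
    """Fit the per-feature min-max grid on the pooled development PFVs."""
    pool = np.atleast_2d(np.asarray(pfv_pool, dtype=float))
    if pool.size == 0:
        raise ValueError("empty PFV pool")
    minima = pool.min(axis=0)
    maxima = pool.max(axis=0)
    for f, (lo, hi) in enumerate(zip(minima, maxima)):
        if lo == hi:
            warnings.warn(
                f"feature {f} is constant ({lo}); quantiser degenerates to one bin"
            )
    return QuantizerModel(minima=minima, maxima=maxima, n_bins=n_bins)


@dataclass
class PFVTable:
    """Cohort-pooled quantised PFVs with voxel back-pointers."""

    values: np.ndarray  # (n, 3) quantised
    pids: np.ndarray  # (n,) patient id per row
    voxel_index: np.ndarray  # (n,) flat index into the patient volume

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.pids) == len(self.voxel_index)):
            raise ValueError("PFV table columns have unequal lengths")


def build_pfv_table(
    cohort_maps: Sequence[PerfusionMaps], quantizer: QuantizerModel
) -> PFVTable:
    """Pool and quantise the ROI voxels of every patient in a cohort."""
    values, pids, vox = [], [], []
    for maps in cohort_maps:
        raw = maps.pfv()
        values.append(quantizer.quantize(raw))
        pids.append(np.repeat(maps.pid, len(raw)))
        vox.append(np.flatnonzero(maps.roi))
    return PFVTable(
        values=np.concatenate(values),
        pids=np.concatenate(pids),
        voxel_index=np.concatenate(vox),
    )


@dataclass
class HabitatModel:
    """Frozen habitat clustering: quantiser + centres in canonical order.

    Canonical order sorts centres lexicographically by (wash-in,
    washout); habitat numbering from clustering is otherwise arbitrary.
    """

    k: int
    centers: np.ndarray  # (k, 3), canonical order
    quantizer: QuantizerModel
    inertia: float
    diagnostics: pd.DataFrame | None = None

    def assign(self, quantized_pfvs: np.ndarray) -> np.ndarray:
        """Label (n, 3) quantised PFVs 1..k by nearest centre.

        Distance ties resolve to the lowest canonical label (argmin
        returns the first minimum over the canonically ordered centres).
        """
        d2 = (
            (np.atleast_2d(quantized_pfvs)[:, None, :] - self.centers[None, :, :]) ** 2
        ).sum(axis=2)
        return d2.argmin(axis=1) + 1

    def to_json(self, path: str | Path) -> None:
        d = {
            "k": self.k,
            "centers": self.centers.tolist(),
            "quantizer": self.quantizer.to_dict(),
            "inertia": self.inertia,
        }
        if self.diagnostics is not None:
            d["diagnostics"] = self.diagnostics.to_dict(orient="list")
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HabitatModel":
        d = json.loads(Path(path).read_text())
        diag = d.get("diagnostics")
        return cls(
            k=int(d["k"]),
            centers=np.asarray(d["centers"]),
            quantizer=QuantizerModel.from_dict(d["quantizer"]),
            inertia=float(d["inertia"]),
            diagnostics=pd.DataFrame(diag) if diag is not None else None,
        )


def canonical_order(centers: np.ndarray) -> np.ndarray:
    """Permutation sorting centres by (wash-in, washout, washout ratio)."""
    return np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0]))


def score_partition(
    values: np.ndarray,
    labels: np.ndarray,
    silhouette_sample: int | None = 2048,
    seed: int = 0,
) -> tuple[float, float]:
    """Calinski-Harabasz and silhouette scores of a hard partition.

    The silhouette is O(n^2), so it is evaluated on a seeded subsample
    (default 2048 voxels); cohort pools reach millions of voxels.
    Degenerate cases (all-singleton clusters) score silhouette 0 per the
    usual per-point convention.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters to score a partition")
    if np.any(counts == 0):
        raise ValueError("empty cluster in partition")
    if np.all(counts == 1):
        # all-singleton partition: zero within-scatter makes CH blow up
        # (reported as inf) and every per-point silhouette is undefined,
        # handled as 0
        return float("inf"), 0.0
    ch = float(calinski_harabasz_score(values, labels))
    kw = {}
    if silhouette_sample is not None and len(values) > silhouette_sample:
        kw = {"sample_size": silhouette_sample, "random_state": seed % (2**31 - 1)}
    sil = float(silhouette_score(values, labels, **kw))
    return ch, sil


def population_kmeans(
    table: PFVTable | np.ndarray,
    k: int,
    n_reps: int = 100,
    seed: int = 0,
    quantizer: QuantizerModel | None = None,
    silhouette_sample: int | None = 2048,
    standardize: bool = False,
    compute_scores: bool = True,
) -> tuple[HabitatModel, pd.DataFrame]:
    """Cohort-level k-means with repeated k-means++ restarts.

    Each repetition runs Lloyd iterations to convergence (relative
    inertia tolerance 1e-6, max 300 iterations) from a k-means++
    initialisation seeded ``seed + rep``; the best-inertia repetition's
    centres are retained and per-repetition scores are returned for k
    selection.
    """
    values = table.values if isinstance(table, PFVTable) else np.asarray(table, float)
    if len(values) < k:
        raise ValueError(f"fewer rows ({len(values)}) than clusters ({k})")
    if len(np.unique(values, axis=0)) < k:
        raise ValueError("fewer distinct rows than clusters")
    work = values
    scale = np.ones(values.shape[1])
    if standardize:
        scale = values.std(axis=0)
        scale[scale == 0] = 1.0
        work = values / scale

    best: KMeans | None = None
    rows = []
    for rep in range(n_reps):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            max_iter=300,
            tol=1e-6,
            random_state=(seed + rep) % (2**31 - 1),
        ).fit(work)
        if compute_scores:
            ch, sil = score_partition(
                work, km.labels_, silhouette_sample=silhouette_sample, seed=seed + rep
            )
        else:
            ch, sil = np.nan, np.nan
        rows.append(
            {"k": k, "rep": rep, "inertia": km.inertia_, "ch": ch, "silhouette": sil}
        )
        if best is None or km.inertia_ < best.inertia_:
            best = km
    centers = best.cluster_centers_ * scale
    order = canonical_order(centers)
    if quantizer is None:
        quantizer = fit_quantizer(values)
    model = HabitatModel(
        k=k,
        centers=centers[order],
        quantizer=quantizer,
        inertia=float(best.inertia_),
    )
    return model, pd.DataFrame(rows)


def sweep_k(
    table: PFVTable | np.ndarray,
    k_range: Sequence[int] = range(2, 33),
    n_reps: int = 100,
    seed: int = 0,
    quantizer: QuantizerModel | None = None,
    silhouette_sample: int | None = 2048,
) -> tuple[dict[int, HabitatModel], pd.DataFrame]:
    """Fit every candidate k; return the models and mean diagnostics."""
    models: dict[int, HabitatModel] = {}
    per_rep = []
    for k in k_range:
        model, scores = population_kmeans(
            table,
            k,
            n_reps=n_reps,
            seed=seed,
            quantizer=quantizer,
            silhouette_sample=silhouette_sample,
        )
        models[k] = model
        per_rep.append(scores)
    all_scores = pd.concat(per_rep, ignore_index=True)
    diag = (
        all_scores.groupby("k")[["ch", "silhouette"]]
        .mean()
        .reset_index()
        .rename(columns={"ch": "mean_ch", "silhouette": "mean_silhouette"})
    )
    return models, diag


def select_k(diagnostics: pd.DataFrame) -> int:
    """Choose the habitat count from averaged CH and silhouette curves.

    The CH candidate is the last k before the averaged Calinski-Harabasz
    curve stops increasing materially — the last step at or before the
    curve's maximum whose gain exceeds 10% of the largest single-step
    gain (with repeated restarts the curve is noisy around its plateau,
    so a literal first-decrease rule is fragile, and noise bumps past
    the peak must not drag the candidate upward).  The candidate must agree with the silhouette ranking's
    top two; otherwise the silhouette winner is taken when it is itself
    among the two best CH values.  Guards: a curve that increases
    through the whole range returns the largest k with a warning; a
    best silhouette below 0.25 signals no substantial cluster structure
    and returns the smallest k with a warning; ties break to smaller k.
    """
    diag = diagnostics.sort_values("k").reset_index(drop=True)
    ks = diag["k"].to_numpy()
    ch = diag["mean_ch"].to_numpy()
    sil = diag["mean_silhouette"].to_numpy()
    if np.all(np.diff(ch) > 0):
        warnings.warn("CH score increases through the whole k range; returning max k")
        return int(ks[-1])
    if np.nanmax(sil) < 0.25:
        warnings.warn(
            "best silhouette below 0.25: no substantial cluster structure; "
            "returning the smallest k"
        )
        return int(ks[0])
    gains = np.diff(ch)
    if gains.max() <= 0:
        warnings.warn("scores decrease from the smallest k; structure may be weak")
        return int(ks[0])
    # elbow: last material gain at or before the CH maximum — late noise
    # bumps past the peak must not drag the candidate upward
    k_max = int(ks[np.argmax(ch)])
    material = (gains > 0.1 * gains.max()) & (ks[1:] <= k_max)
    k_elbow = int(ks[1:][material][-1]) if material.any() else k_max
    sil_rank = ks[np.argsort(sil, kind="stable")[::-1]]
    ch_rank = ks[np.argsort(ch, kind="stable")[::-1]]
    if k_elbow in sil_rank[:2]:
        return k_elbow
    if sil_rank[0] in ch_rank[:2]:
        return int(sil_rank[0])
    warnings.warn(
        "CH and silhouette rankings disagree; keeping the CH elbow "
        f"k={k_elbow} (silhouette favoured k={int(sil_rank[0])})"
    )
    return k_elbow


@dataclass
class HabitatMap:
    """Per-patient habitat label volume with habitat voxel proportions."""

    pid: str
    labels: np.ndarray  # 0 outside ROI, 1..k inside
    proportions: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        s = self.proportions.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"habitat proportions sum to {s}, expected 1")


def build_habitat_map(maps: PerfusionMaps, model: HabitatModel) -> HabitatMap:
    """Label each ROI voxel of a patient by its nearest habitat centre."""
    raw = maps.pfv()
    quantized = model.quantizer.quantize(raw)
    assigned = model.assign(quantized)
    labels = np.zeros(maps.roi.shape, dtype=np.int16)
    labels[maps.roi] = assigned
    counts = np.bincount(assigned, minlength=model.k + 1)[1:]
    return HabitatMap(
        pid=maps.pid,
        labels=labels,
        proportions=counts / counts.sum(),
        spacing=maps.spacing,
    )


def cohort_proportions(habitat_maps: Sequence[HabitatMap], k: int) -> np.ndarray:
    """Voxel fraction of each habitat pooled over a cohort."""
    counts = np.zeros(k)
    for hm in habitat_maps:
        inside = hm.labels[hm.labels > 0]
        counts += np.bincount(inside, minlength=k + 1)[1:]
    return counts / counts.sum()


def match_centers(
    centers: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Match recovered centres to reference rows by bipartite assignment.

    Returns ``perm`` with ``centers[perm[i]]`` the recovered centre
    matched to ``reference[i]`` (minimum total Euclidean distance).
    """
    cost = np.linalg.norm(
        np.asarray(reference)[:, None, :] - np.asarray(centers)[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(reference), dtype=int)
    perm[rows] = cols
    return perm
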