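"""Spatial-heterogeneity features of habitat label maps and tumour ROIs.

The habitat map is an integer label volume; treating the labels as gray
levels with bin size one, the module computes the standard IBSI-style
texture descriptors: 24 gray-level co-occurrence matrix (GLCM) features
(distance 1, 13 unique 3D directions, symmetric matrices, per-direction
features averaged), 16 gray-level size-zone matrix (GLSZM) features
(26-connected zones), 4 first-order histogram features, and 14
mesh-based 3D shape features of the ROI — 58 features in total, plus
the per-habitat volume proportions.

The same texture machinery applied to fixed-bin-count discretisations of
continuous images provides the whole-tumour feature panels used by the
conventional radiomics comparators.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

__all__ = [
    "GLCM_FEATURES",
    "GLSZM_FEATURES",
    "HISTOGRAM_FEATURES",
    "SHAPE_FEATURES",
    "HABITAT_FEATURE_COUNT",
    "glcm_features",
    "glszm_features",
    "histogram_features",
    "shape_features",
    "habitat_proportions",
    "extract_habitat_features",
    "whole_tumor_features",
    "z_score_normalize",
]

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)

GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

HISTOGRAM_FEATURES = ("Entropy", "Uniformity", "Skewness", "Kurtosis")

SHAPE_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)

HABITAT_FEATURE_COUNT = (
    len(HISTOGRAM_FEATURES) + len(GLCM_FEATURES) + len(GLSZM_FEATURES)
    + len(SHAPE_FEATURES)
)  # = 58

# the 13 unique 3D direction vectors at distance 1 (up to sign)
_DIRECTIONS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def _shifted_pairs(volume: np.ndarray, mask: np.ndarray, offset):
    """Gray values of all voxel pairs (v, v+offset) with both ends in the mask."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, volume.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    a, b = volume[tuple(sl_a)], volume[tuple(sl_b)]
    ok = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    return a[ok], b[ok]


def _glcm_one_direction(gray_a: np.ndarray, gray_b: np.ndarray):
    """Symmetric normalised GLCM over the levels co-occurring in one direction."""
    levels, inv = np.unique(np.concatenate([gray_a, gray_b]), return_inverse=True)
    ia, ib = inv[: len(gray_a)], inv[len(gray_a):]
    n = len(levels)
    counts = np.zeros((n, n))
    np.add.at(counts, (ia, ib), 1.0)
    counts = counts + counts.T  # symmetrise: count each pair in both orders
    return levels.astype(float), counts / counts.sum()


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _glcm_features_one(levels: np.ndarray, p: np.ndarray) -> dict[str, float]:
    ng = len(levels)
    i = levels[:, None]
    j = levels[None, :]
    px = p.sum(axis=1)
    mu = float((levels * px).sum())
    sigma2 = float((((levels - mu) ** 2) * px).sum())
    sigma = np.sqrt(sigma2)

    diff = np.abs(i - j)
    d_vals, d_inv = np.unique(diff.ravel(), return_inverse=True)
    p_d = np.bincount(d_inv, weights=p.ravel())
    s_vals, s_inv = np.unique((i + j).ravel(), return_inverse=True)
    p_s = np.bincount(s_inv, weights=p.ravel())
    da = float((d_vals * p_d).sum())

    hx = _entropy2(px)
    hxy = _entropy2(p.ravel())
    outer = px[:, None] * px[None, :]
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-(p[pos] * np.log2(outer[pos])).sum())
    hxy2 = _entropy2(outer.ravel())

    f: dict[str, float] = {}
    f["Autocorrelation"] = float((p * i * j).sum())
    f["JointAverage"] = mu
    dev = i + j - 2 * mu
    f["ClusterProminence"] = float((p * dev**4).sum())
    f["ClusterShade"] = float((p * dev**3).sum())
    f["ClusterTendency"] = float((p * dev**2).sum())
    f["Contrast"] = float((p * (i - j) ** 2).sum())
    f["Correlation"] = (
        1.0 if sigma2 <= 0 else float(((p * i * j).sum() - mu * mu) / sigma2)
    )
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = _entropy2(p_d)
    f["DifferenceVariance"] = float((p_d * (d_vals - da) ** 2).sum())
    f["JointEnergy"] = float((p**2).sum())
    f["JointEntropy"] = hxy
    f["Imc1"] = 0.0 if hx <= 0 else float((hxy - hxy1) / hx)
    f["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    f["Idm"] = float((p / (1.0 + (i - j) ** 2)).sum())
    f["Idmn"] = float((p / (1.0 + ((i - j) / ng) ** 2)).sum())
    f["Id"] = float((p / (1.0 + diff)).sum())
    f["Idn"] = float((p / (1.0 + diff / ng)).sum())
    off = diff > 0
    f["InverseVariance"] = float((p[off] / diff[off] ** 2).sum())
    f["MaximumProbability"] = float(p.max())
    f["SumAverage"] = float((s_vals * p_s).sum())
    f["SumEntropy"] = _entropy2(p_s)
    f["SumSquares"] = sigma2
    if ng == 1:
        f["MCC"] = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p / px[None, :]) @ (p / px[:, None]).T
        q = np.nan_to_num(q)
        eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        f["MCC"] = float(np.sqrt(max(0.0, eig[1])))
    return f


def glcm_features(
    label_map: np.ndarray, n_levels: int | None = None
) -> dict[str, float]:
    """24 GLCM features of a habitat label map, averaged over directions.

    Labels serve directly as gray levels (bin size one); voxels with
    label 0 are outside the ROI.  For each of the 13 unique distance-1
    directions a symmetric co-occurrence probability matrix over the
    levels present in that direction is built, each feature is computed
    per direction, and per-direction values are averaged.
    """
    mask = label_map > 0
    if not mask.any():
        raise ValueError("empty ROI")
    per_dir: list[dict[str, float]] = []
    for offset in _DIRECTIONS:
        a, b = _shifted_pairs(label_map, mask, offset)
        if len(a) == 0:
            continue
        levels, p = _glcm_one_direction(a.astype(float), b.astype(float))
        per_dir.append(_glcm_features_one(levels, p))
    if not per_dir:
        raise ValueError("no voxel pairs in any direction; ROI too small")
    return {
        f"glcm_{name}": float(np.mean([d[name] for d in per_dir]))
        for name in GLCM_FEATURES
    }


def _size_zone_matrix(label_map: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(levels, sizes, counts) triplets of 26-connected equal-label zones."""
    structure = np.ones((3, 3, 3), dtype=int)
    levels = np.unique(label_map[label_map > 0])
    rows: dict[tuple[float, int], int] = {}
    for lev in levels:
        comp, n = ndimage.label(label_map == lev, structure=structure)
        sizes = np.bincount(comp.ravel())[1:]
        for s in sizes:
            rows[(float(lev), int(s))] = rows.get((float(lev), int(s)), 0) + 1
    keys = sorted(rows)
    g = np.array([k[0] for k in keys])
    s = np.array([k[1] for k in keys], dtype=float)
    c = np.array([rows[k] for k in keys], dtype=float)
    return g, s, c


def glszm_features(
    label_map: np.ndarray, n_levels: int | None = None
) -> dict[str, float]:
    """16 GLSZM features of a habitat label map (26-connected zones)."""
    mask = label_map > 0
    if not mask.any():
        raise ValueError("empty ROI")
    g, s, c = _size_zone_matrix(label_map)
    nz = c.sum()
    npix = float(mask.sum())
    p = c / nz
    mu_g = float((p * g).sum())
    mu_s = float((p * s).sum())
    # per-level and per-size marginal squared sums
    lev_tot = pd.Series(c).groupby(g).sum().to_numpy()
    size_tot = pd.Series(c).groupby(s).sum().to_numpy()
    f = {
        "SmallAreaEmphasis": float((c / s**2).sum() / nz),
        "LargeAreaEmphasis": float((c * s**2).sum() / nz),
        "GrayLevelNonUniformity": float((lev_tot**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((lev_tot**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((size_tot**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((size_tot**2).sum() / nz**2),
        "ZonePercentage": float(nz / npix),
        "GrayLevelVariance": float((p * (g - mu_g) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": _entropy2(p),
        "LowGrayLevelZoneEmphasis": float((c / g**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((c * g**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((c / (g**2 * s**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((c * g**2 / s**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((c * s**2 / g**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((c * g**2 * s**2).sum() / nz),
    }
    return {f"glszm_{name}": f[name] for name in GLSZM_FEATURES}


def histogram_features(label_map: np.ndarray) -> dict[str, float]:
    """First-order statistics of the label histogram (bin size one).

    Entropy and uniformity use the discrete label probabilities;
    skewness and kurtosis are the standardised third and fourth moments
    (Pearson kurtosis, no -3 offset).  A single-label map scores entropy
    0, uniformity 1, and skewness/kurtosis 0 by the degenerate-moment
    convention.
    """
    vals = label_map[label_map > 0].astype(float)
    if vals.size == 0:
        raise ValueError("empty ROI")
    _, counts = np.unique(vals, return_counts=True)
    p = counts / counts.sum()
    mu = vals.mean()
    m2 = ((vals - mu) ** 2).mean()
    if m2 > 0:
        skew = ((vals - mu) ** 3).mean() / m2**1.5
        kurt = ((vals - mu) ** 4).mean() / m2**2
    else:
        skew, kurt = 0.0, 0.0
    return {
        "hist_Entropy": _entropy2(p),
        "hist_Uniformity": float((p**2).sum()),
        "hist_Skewness": float(skew),
        "hist_Kurtosis": float(kurt),
    }


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    pts = np.unique(points, axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except Exception:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: np.ndarray, spacing: Sequence[float]) -> dict[str, float]:
    """14 mesh-based 3D shape features of a binary tumour ROI.

    Surface area and mesh volume come from a marching-cubes
    triangulation in physical units; axis lengths are 4*sqrt of the
    principal eigenvalues of the physical voxel-coordinate covariance.
    Masks too small to mesh fall back to voxel-based approximations
    with a warning.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty ROI")
    spacing = np.asarray(spacing, dtype=float)
    voxel_volume = float(np.prod(spacing))
    n = int(mask.sum())
    coords = np.argwhere(mask) * spacing

    try:
        if n < 2:
            raise ValueError("mask below mesh minimum")
        # anti-alias the binary mask before meshing: a raw 0/1 volume
        # yields a staircase surface that overestimates curved areas
        padded = np.pad(mask.astype(float), 2)
        smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
        if smoothed.max() <= 0.5:  # thin structure eroded away; mesh raw mask
            smoothed = padded
        verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=spacing)
        area = float(measure.mesh_surface_area(verts, faces))
        tri = verts[faces]
        volume = float(abs(np.einsum("ij,ij->i", tri[:, 0],
                                     np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
        mesh_ok = volume > 0 and area > 0
    except Exception:
        mesh_ok = False
    if not mesh_ok:
        warnings.warn("mask too small to mesh; using voxel-based shape fallback")
        volume = n * voxel_volume
        # total exposed voxel-face area
        area = 0.0
        for axis in range(3):
            face = voxel_volume / spacing[axis]
            padded = np.pad(mask, 1)
            diff = np.diff(padded.astype(int), axis=axis)
            area += np.abs(diff).sum() * face
        verts = coords + spacing / 2.0

    sphericity = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area

    if n > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)

    return {
        "shape_MeshVolume": volume,
        "shape_VoxelVolume": n * voxel_volume,
        "shape_SurfaceArea": area,
        "shape_SurfaceVolumeRatio": area / volume,
        "shape_Sphericity": float(sphericity),
        "shape_Maximum3DDiameter": _max_pairwise(verts),
        "shape_Maximum2DDiameterSlice": _max_pairwise(verts[:, :2]),
        "shape_Maximum2DDiameterColumn": _max_pairwise(verts[:, [0, 2]]),
        "shape_Maximum2DDiameterRow": _max_pairwise(verts[:, 1:]),
        "shape_MajorAxisLength": float(major),
        "shape_MinorAxisLength": float(minor),
        "shape_LeastAxisLength": float(least),
        "shape_Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0,
        "shape_Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0,
    }


def habitat_proportions(label_map: np.ndarray, k: int) -> dict[str, float]:
    """Voxel fraction of each habitat 1..k inside the ROI."""
    inside = label_map[label_map > 0]
    if inside.size == 0:
        raise ValueError("empty ROI")
    counts = np.bincount(inside.astype(int), minlength=k + 1)[1:k + 1]
    props = counts / counts.sum()
    return {f"prop_habitat_{i + 1}": float(p) for i, p in enumerate(props)}


def extract_habitat_features(
    label_map: np.ndarray, spacing: Sequence[float], k: int
) -> dict[str, float]:
    """The full 58-feature heterogeneity panel plus k habitat proportions."""
    out: dict[str, float] = {}
    out.update(histogram_features(label_map))
    out.update(glcm_features(label_map, n_levels=k))
    out.update(glszm_features(label_map, n_levels=k))
    out.update(shape_features(label_map > 0, spacing))
    out.update(habitat_proportions(label_map, k))
    return out


def discretize_fixed_bins(
    image: np.ndarray, roi: np.ndarray, n_bins: int = 32
) -> np.ndarray:
    """Fixed-bin-count discretisation of a continuous image over the ROI range."""
    out = np.zeros(image.shape, dtype=np.int32)
    vals = image[roi]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        warnings.warn("constant image inside ROI; all voxels map to one level")
        out[roi] = 1
        return out
    width = (hi - lo) / n_bins
    lev = np.floor((image[roi] - lo) / width).astype(np.int32) + 1
    out[roi] = np.clip(lev, 1, n_bins)
    return out


def whole_tumor_features(
    image: np.ndarray,
    roi: np.ndarray,
    spacing: Sequence[float] | None = None,
    n_bins: int = 32,
    panels: Sequence[str] = ("glcm",),
    prefix: str = "",
) -> dict[str, float]:
    """Conventional whole-tumour texture features of a continuous image.

    The image is discretised to ``n_bins`` fixed bins over the ROI
    intensity range, then the requested texture panels are computed on
    the discretised map.  The default single-panel composition (24 GLCM
    features per image) gives 72 features over a three-image analysis.
    """
    if not roi.any():
        raise ValueError("empty ROI")
    disc = discretize_fixed_bins(image, roi, n_bins=n_bins)
    out: dict[str, float] = {}
    for panel in panels:
        if panel == "glcm":
            vals = glcm_features(disc, n_levels=n_bins)
        elif panel == "glszm":
            vals = glszm_features(disc, n_levels=n_bins)
        elif panel == "histogram":
            vals = histogram_features(disc)
        else:
            raise ValueError(f"unknown panel {panel!r}")
        out.update(vals)
    if prefix:
        out = {f"{prefix}{k}": v for k, v in out.items()}
    return out


def z_score_normalize(
    features: pd.DataFrame, stats: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score features using development-cohort statistics.

    When ``stats`` is None the mean/SD are estimated from ``features``
    (the development cohort) and returned for reuse on the validation
    cohort.  Zero-SD features are dropped with a warning.
    """
    if stats is None:
        stats = pd.DataFrame(
            {"mean": features.mean(), "sd": features.std(ddof=1)}
        )
    dead = stats.index[stats["sd"] == 0].tolist()
    missing = [c for c in stats.index if c not in features.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing}")
    if dead:
        warnings.warn(f"dropping constant features: {dead}")
    keep = [c for c in stats.index if c not in dead]
    z = (features[keep] - stats.loc[keep, "mean"]) / stats.loc[keep, "sd"]
    return z, stats
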