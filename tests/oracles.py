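"""Independent brute-force oracles for texture, clustering and survival checks.

Everything here is written as literal loop-based translations of the
feature and statistic definitions, deliberately sharing no code with the
package implementation.  They are only feasible on tiny instances.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

_OFFSETS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def _log2(x: float) -> float:
    return math.log(x, 2)


def glcm_oracle(volume: np.ndarray) -> dict[str, float]:
    """Per-direction GLCM features via exhaustive voxel-pair enumeration."""
    nx, ny, nz = volume.shape
    per_dir: list[dict[str, float]] = []
    for off in _OFFSETS_13:
        pairs: dict[tuple[float, float], int] = defaultdict(int)
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if volume[x, y, z] <= 0:
                        continue
                    u, v, w = x + off[0], y + off[1], z + off[2]
                    if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                        continue
                    if volume[u, v, w] <= 0:
                        continue
                    a, b = float(volume[x, y, z]), float(volume[u, v, w])
                    pairs[(a, b)] += 1
                    pairs[(b, a)] += 1  # symmetric matrix
        if not pairs:
            continue
        per_dir.append(_glcm_features_from_pairs(pairs))
    assert per_dir, "oracle: no voxel pairs"
    return {
        k: sum(d[k] for d in per_dir) / len(per_dir) for k in per_dir[0]
    }


def _glcm_features_from_pairs(pairs: dict[tuple[float, float], int]) -> dict[str, float]:
    total = sum(pairs.values())
    levels = sorted({a for a, _ in pairs} | {b for _, b in pairs})
    ng = len(levels)
    p = {(a, b): c / total for (a, b), c in pairs.items()}

    def psum(fn):
        return sum(fn(a, b, q) for (a, b), q in p.items())

    px = {g: sum(q for (a, _), q in p.items() if a == g) for g in levels}
    mu = sum(g * px[g] for g in levels)
    sigma2 = sum((g - mu) ** 2 * px[g] for g in levels)

    p_diff: dict[float, float] = defaultdict(float)
    p_sum: dict[float, float] = defaultdict(float)
    for (a, b), q in p.items():
        p_diff[abs(a - b)] += q
        p_sum[a + b] += q
    da = sum(k * q for k, q in p_diff.items())

    hx = -sum(q * _log2(q) for q in px.values() if q > 0)
    hxy = -sum(q * _log2(q) for q in p.values() if q > 0)
    hxy1 = -sum(
        q * _log2(px[a] * px[b]) for (a, b), q in p.items() if px[a] * px[b] > 0
    )
    hxy2 = -sum(
        px[a] * px[b] * _log2(px[a] * px[b])
        for a in levels
        for b in levels
        if px[a] * px[b] > 0
    )

    f: dict[str, float] = {}
    f["Autocorrelation"] = psum(lambda a, b, q: q * a * b)
    f["JointAverage"] = mu
    f["ClusterProminence"] = psum(lambda a, b, q: q * (a + b - 2 * mu) ** 4)
    f["ClusterShade"] = psum(lambda a, b, q: q * (a + b - 2 * mu) ** 3)
    f["ClusterTendency"] = psum(lambda a, b, q: q * (a + b - 2 * mu) ** 2)
    f["Contrast"] = psum(lambda a, b, q: q * (a - b) ** 2)
    f["Correlation"] = (
        1.0 if sigma2 <= 0
        else (psum(lambda a, b, q: q * a * b) - mu * mu) / sigma2
    )
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(q * _log2(q) for q in p_diff.values() if q > 0)
    f["DifferenceVariance"] = sum(q * (k - da) ** 2 for k, q in p_diff.items())
    f["JointEnergy"] = psum(lambda a, b, q: q * q)
    f["JointEntropy"] = hxy
    f["Imc1"] = 0.0 if hx <= 0 else (hxy - hxy1) / hx
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["Idm"] = psum(lambda a, b, q: q / (1.0 + (a - b) ** 2))
    f["Idmn"] = psum(lambda a, b, q: q / (1.0 + ((a - b) / ng) ** 2))
    f["Id"] = psum(lambda a, b, q: q / (1.0 + abs(a - b)))
    f["Idn"] = psum(lambda a, b, q: q / (1.0 + abs(a - b) / ng))
    f["InverseVariance"] = sum(
        q / (a - b) ** 2 for (a, b), q in p.items() if a != b
    )
    f["MaximumProbability"] = max(p.values())
    f["SumAverage"] = sum(k * q for k, q in p_sum.items())
    f["SumEntropy"] = -sum(q * _log2(q) for q in p_sum.values() if q > 0)
    f["SumSquares"] = sigma2
    if ng == 1:
        f["MCC"] = 1.0
    else:
        qmat = np.zeros((ng, ng))
        for i, gi in enumerate(levels):
            for j, gj in enumerate(levels):
                s = 0.0
                for k, gk in enumerate(levels):
                    if px[gi] > 0 and px[gk] > 0:
                        s += p.get((gi, gk), 0.0) * p.get((gj, gk), 0.0) / (
                            px[gi] * px[gk]
                        )
                qmat[i, j] = s
        eig = sorted(np.real(np.linalg.eigvals(qmat)), reverse=True)
        f["MCC"] = math.sqrt(max(0.0, eig[1]))
    return f


def glszm_oracle(volume: np.ndarray) -> dict[str, float]:
    """GLSZM features via explicit flood-fill over 26-neighbourhoods."""
    nx, ny, nz = volume.shape
    visited = np.zeros(volume.shape, dtype=bool)
    zones: list[tuple[float, int]] = []
    npix = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if volume[x, y, z] <= 0:
                    continue
                npix += 1
                if visited[x, y, z]:
                    continue
                level = volume[x, y, z]
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                if dx == dy == dz == 0:
                                    continue
                                u, v, w = cx + dx, cy + dy, cz + dz
                                if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                                    continue
                                if visited[u, v, w] or volume[u, v, w] != level:
                                    continue
                                visited[u, v, w] = True
                                stack.append((u, v, w))
                zones.append((float(level), size))
    nz_total = len(zones)
    f: dict[str, float] = {}
    f["SmallAreaEmphasis"] = sum(1.0 / s**2 for _, s in zones) / nz_total
    f["LargeAreaEmphasis"] = sum(float(s) ** 2 for _, s in zones) / nz_total
    by_level: dict[float, int] = defaultdict(int)
    by_size: dict[int, int] = defaultdict(int)
    for g, s in zones:
        by_level[g] += 1
        by_size[s] += 1
    f["GrayLevelNonUniformity"] = sum(c**2 for c in by_level.values()) / nz_total
    f["GrayLevelNonUniformityNormalized"] = (
        sum(c**2 for c in by_level.values()) / nz_total**2
    )
    f["SizeZoneNonUniformity"] = sum(c**2 for c in by_size.values()) / nz_total
    f["SizeZoneNonUniformityNormalized"] = (
        sum(c**2 for c in by_size.values()) / nz_total**2
    )
    f["ZonePercentage"] = nz_total / npix
    mu_g = sum(g for g, _ in zones) / nz_total
    mu_s = sum(s for _, s in zones) / nz_total
    f["GrayLevelVariance"] = sum((g - mu_g) ** 2 for g, _ in zones) / nz_total
    f["ZoneVariance"] = sum((s - mu_s) ** 2 for _, s in zones) / nz_total
    probs: dict[tuple[float, int], float] = defaultdict(float)
    for g, s in zones:
        probs[(g, s)] += 1.0 / nz_total
    f["ZoneEntropy"] = -sum(q * _log2(q) for q in probs.values())
    f["LowGrayLevelZoneEmphasis"] = sum(1.0 / g**2 for g, _ in zones) / nz_total
    f["HighGrayLevelZoneEmphasis"] = sum(g**2 for g, _ in zones) / nz_total
    f["SmallAreaLowGrayLevelEmphasis"] = (
        sum(1.0 / (g**2 * s**2) for g, s in zones) / nz_total
    )
    f["SmallAreaHighGrayLevelEmphasis"] = (
        sum(g**2 / s**2 for g, s in zones) / nz_total
    )
    f["LargeAreaLowGrayLevelEmphasis"] = (
        sum(float(s) ** 2 / g**2 for g, s in zones) / nz_total
    )
    f["LargeAreaHighGrayLevelEmphasis"] = (
        sum(g**2 * float(s) ** 2 for g, s in zones) / nz_total
    )
    return f


def c_index_oracle(scores, time, event) -> float:
    """Harrell's C by exhaustive ordered-pair enumeration."""
    conc = ties = usable = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if event[i] != 1 or not (time[j] > time[i]):
                continue
            usable += 1
            if scores[i] > scores[j]:
                conc += 1
            elif scores[i] == scores[j]:
                ties += 1
    assert usable > 0
    return (conc + 0.5 * ties) / usable


def calinski_harabasz_oracle(x: np.ndarray, labels: np.ndarray) -> float:
    """CH index from explicit between/within scatter sums."""
    x = np.asarray(x, float)
    n = len(x)
    ks = sorted(set(labels))
    grand = x.mean(axis=0)
    b = w = 0.0
    for k in ks:
        pts = x[np.asarray(labels) == k]
        c = pts.mean(axis=0)
        b += len(pts) * float(((c - grand) ** 2).sum())
        w += float(((pts - c) ** 2).sum())
    return (b / (len(ks) - 1)) / (w / (n - len(ks)))


def silhouette_oracle(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette by explicit per-point neighbour averaging."""
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    n = len(x)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(x[i] - x[j]) for j in range(n) if labels[j] == k])
            for k in set(labels)
            if k != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))
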