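"""Per-voxel statistical and gray-level co-occurrence (GLCM) texture features.

Tumor and normal parenchyma overlap in raw HU but differ in local texture, so
each voxel inside the liver is described by a 10-component feature vector
computed over its 11x11x11 neighborhood (clipped at the volume border):

    statistical : mean HU, std, skewness, kurtosis, median
    GLCM        : contrast, correlation, entropy (bits), energy, homogeneity

The GLCM is accumulated over the 13 unique unit-displacement directions of the
3-D lattice, symmetrized, and normalized to a joint probability matrix over
``levels`` uniformly quantized gray levels within a fixed HU window.

Two code paths produce identical numbers: :func:`feature_vector` computes one
voxel's features with plain numpy (and composes :func:`glcm_3d` /
:func:`haralick_features`), while :func:`feature_map` runs a numba-compiled
kernel over every ROI voxel for whole-liver extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ContractError
from .io import BinaryMask, CTVolume

__all__ = [
    "FEATURE_NAMES",
    "UNIT_OFFSETS_13",
    "GLCM",
    "quantize",
    "glcm_3d",
    "haralick_features",
    "statistical_features",
    "feature_vector",
    "feature_map",
]

FEATURE_NAMES = (
    "mean",
    "std",
    "skewness",
    "kurtosis",
    "median",
    "contrast",
    "correlation",
    "entropy",
    "energy",
    "homogeneity",
)

DEFAULT_LEVELS = 32
DEFAULT_HU_WINDOW = (-100.0, 300.0)
DEFAULT_WINDOW = 11

#: the 13 unique distance-1 displacement directions of the 26-neighborhood
#: (one representative per +/- pair, lexicographically positive)
UNIT_OFFSETS_13 = np.array(
    [
        (0, 0, 1),
        (0, 1, -1),
        (0, 1, 0),
        (0, 1, 1),
        (1, -1, -1),
        (1, -1, 0),
        (1, -1, 1),
        (1, 0, -1),
        (1, 0, 0),
        (1, 0, 1),
        (1, 1, -1),
        (1, 1, 0),
        (1, 1, 1),
    ],
    dtype=np.int64,
)


@dataclass
class GLCM:
    """A normalized gray-level co-occurrence matrix."""

    probabilities: np.ndarray
    levels: int
    offsets: np.ndarray
    symmetric: bool

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.shape != (self.levels, self.levels):
            raise ContractError(f"GLCM shape {p.shape} != ({self.levels}, {self.levels})")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ContractError("GLCM entries must be >= 0 and sum to 1")
        self.probabilities = p


def quantize(
    data: np.ndarray | CTVolume,
    levels: int = DEFAULT_LEVELS,
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
) -> np.ndarray:
    """Uniformly bin HU values into ``levels`` integer gray levels.

    Values are clipped to ``hu_window`` first; HU == lo maps to level 0 and
    HU >= hi maps to ``levels - 1``.  The mapping is monotone in HU.
    """
    if levels < 2:
        raise ContractError("levels must be >= 2")
    lo, hi = map(float, hu_window)
    if not lo < hi:
        raise ContractError(f"hu_window must satisfy lo < hi, got {hu_window}")
    arr = data.data if isinstance(data, CTVolume) else np.asarray(data, dtype=np.float64)
    idx = np.floor((arr - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(idx, 0, levels - 1)


def glcm_3d(
    patch: np.ndarray,
    offsets: np.ndarray = UNIT_OFFSETS_13,
    symmetric: bool = True,
    levels: int | None = None,
) -> GLCM:
    """Co-occurrence matrix of a quantized 3-D patch, pooled over offsets.

    For every in-bounds voxel ``p`` and offset ``o`` the pair
    ``(patch[p], patch[p + o])`` is counted; with ``symmetric=True`` the
    transpose is added, making the matrix symmetric.  Counts are normalized
    to probabilities.
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ContractError("patch is empty")
    offsets = np.atleast_2d(np.asarray(offsets, dtype=np.int64))
    if levels is None:
        levels = int(patch.max()) + 1
    counts = np.zeros((levels, levels), dtype=np.float64)
    shape = patch.shape
    any_pairs = False
    for off in offsets:
        if np.all(off == 0):
            raise ContractError("offset (0,0,0) is not allowed")
        if np.any(np.abs(off) >= np.asarray(shape)):
            raise ContractError(f"offset {tuple(off)} exceeds patch extent {shape}")
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)
        )
        a = patch[src].ravel()
        b = patch[dst].ravel()
        if a.size == 0:
            continue
        any_pairs = True
        np.add.at(counts, (a, b), 1.0)
    if not any_pairs:
        raise ContractError("no co-occurring pairs for the given offsets")
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts / counts.sum(), levels=levels, offsets=offsets, symmetric=symmetric)


def haralick_features(glcm: GLCM) -> dict[str, float]:
    """Contrast, correlation, entropy (bits), energy and homogeneity of a GLCM.

    Correlation of a zero-variance (single-level) matrix is defined as 0.
    """
    p = glcm.probabilities
    L = glcm.levels
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float((i * p_i).sum())
    mu_j = float((i * p_j).sum())
    var_i = float(((i - mu_i) ** 2 * p_i).sum())
    var_j = float(((i - mu_j) ** 2 * p_j).sum())
    denom = np.sqrt(var_i * var_j)
    if denom > 0:
        correlation = float(((ii - mu_i) * (jj - mu_j) * p).sum() / denom)
    else:
        correlation = 0.0
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    return {
        "contrast": contrast,
        "correlation": correlation,
        "entropy": entropy,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def statistical_features(patch_hu: np.ndarray) -> dict[str, float]:
    """Mean, population std, skewness, excess kurtosis and median of raw HU.

    Skewness and kurtosis of a constant patch are defined as 0.
    """
    x = np.asarray(patch_hu, dtype=np.float64).ravel()
    if x.size == 0:
        raise ContractError("patch is empty")
    mean = float(x.mean())
    d = x - mean
    m2 = float((d**2).mean())
    if m2 > 0:
        m3 = float((d**3).mean())
        m4 = float((d**4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "mean": mean,
        "std": float(np.sqrt(m2)),
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(np.median(x)),
    }


def feature_vector(
    patch_hu: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
    offsets: np.ndarray = UNIT_OFFSETS_13,
) -> np.ndarray:
    """The 10-feature vector of a single HU patch, in :data:`FEATURE_NAMES` order."""
    stats = statistical_features(patch_hu)
    q = quantize(patch_hu, levels=levels, hu_window=hu_window)
    har = haralick_features(glcm_3d(q, offsets=offsets, symmetric=True, levels=levels))
    merged = {**stats, **har}
    return np.array([merged[name] for name in FEATURE_NAMES], dtype=np.float64)


@njit(cache=False)
def _feature_kernel(hu, q, coords, half, offsets, levels):  # pragma: no cover - numba
    n = coords.shape[0]
    nz, ny, nx = hu.shape
    out = np.empty((n, 10), dtype=np.float64)
    counts = np.empty((levels, levels), dtype=np.float64)
    for v in range(n):
        cz, cy, cx = coords[v, 0], coords[v, 1], coords[v, 2]
        z0 = max(0, cz - half)
        z1 = min(nz, cz + half + 1)
        y0 = max(0, cy - half)
        y1 = min(ny, cy + half + 1)
        x0 = max(0, cx - half)
        x1 = min(nx, cx + half + 1)
        m = (z1 - z0) * (y1 - y0) * (x1 - x0)

        # statistical moments + median on the raw HU neighborhood
        buf = np.empty(m, dtype=np.float64)
        t = 0
        for z in range(z0, z1):
            for y in range(y0, y1):
                for x in range(x0, x1):
                    buf[t] = hu[z, y, x]
                    t += 1
        mean = buf.mean()
        m2 = 0.0
        m3 = 0.0
        m4 = 0.0
        for t in range(m):
            d = buf[t] - mean
            d2 = d * d
            m2 += d2
            m3 += d2 * d
            m4 += d2 * d2
        m2 /= m
        m3 /= m
        m4 /= m
        if m2 > 0:
            skew = m3 / m2**1.5
            kurt = m4 / (m2 * m2) - 3.0
        else:
            skew = 0.0
            kurt = 0.0
        median = np.median(buf)

        # symmetric pooled GLCM over the quantized neighborhood
        counts[:, :] = 0.0
        for k in range(offsets.shape[0]):
            oz, oy, ox = offsets[k, 0], offsets[k, 1], offsets[k, 2]
            for z in range(max(z0, z0 - oz), min(z1, z1 - oz)):
                for y in range(max(y0, y0 - oy), min(y1, y1 - oy)):
                    for x in range(max(x0, x0 - ox), min(x1, x1 - ox)):
                        a = q[z, y, x]
                        b = q[z + oz, y + oy, x + ox]
                        counts[a, b] += 1.0
                        counts[b, a] += 1.0
        total = counts.sum()
        contrast = 0.0
        entropy = 0.0
        energy = 0.0
        homogeneity = 0.0
        mu_i = 0.0
        mu_j = 0.0
        for a in range(levels):
            for b in range(levels):
                if counts[a, b] == 0.0:
                    continue
                p = counts[a, b] / total
                diff = a - b
                contrast += p * diff * diff
                entropy -= p * np.log2(p)
                energy += p * p
                homogeneity += p / (1.0 + abs(diff))
                mu_i += a * p
                mu_j += b * p
        var_i = 0.0
        var_j = 0.0
        cov = 0.0
        for a in range(levels):
            for b in range(levels):
                if counts[a, b] == 0.0:
                    continue
                p = counts[a, b] / total
                var_i += (a - mu_i) * (a - mu_i) * p
                var_j += (b - mu_j) * (b - mu_j) * p
                cov += (a - mu_i) * (b - mu_j) * p
        denom = np.sqrt(var_i * var_j)
        correlation = cov / denom if denom > 0 else 0.0

        out[v, 0] = mean
        out[v, 1] = np.sqrt(m2)
        out[v, 2] = skew
        out[v, 3] = kurt
        out[v, 4] = median
        out[v, 5] = contrast
        out[v, 6] = correlation
        out[v, 7] = entropy
        out[v, 8] = energy
        out[v, 9] = homogeneity
    return out


def feature_map(
    volume: CTVolume,
    roi: BinaryMask,
    window: int = DEFAULT_WINDOW,
    levels: int = DEFAULT_LEVELS,
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
    offsets: np.ndarray = UNIT_OFFSETS_13,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature vectors for every ROI voxel.

    Returns ``(coords, features)`` where ``coords`` is the ``(n, 3)`` array of
    ROI voxel indices (argwhere order) and ``features`` the matching
    ``(n, 10)`` array in :data:`FEATURE_NAMES` order.  Neighborhoods are
    clipped at the volume border rather than padded.
    """
    if window % 2 == 0 or window < 1:
        raise ContractError(f"window must be odd and positive, got {window}")
    roi.check_aligned(volume)
    if not roi.data.any():
        raise ContractError("ROI is empty")
    coords = np.argwhere(roi.data).astype(np.int64)
    q = quantize(volume.data, levels=levels, hu_window=hu_window).astype(np.int64)
    feats = _feature_kernel(
        np.ascontiguousarray(volume.data),
        np.ascontiguousarray(q),
        coords,
        window // 2,
        np.ascontiguousarray(np.asarray(offsets, dtype=np.int64)),
        int(levels),
    )
    return coords, feats
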