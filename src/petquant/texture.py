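"""Whole-brain 3D co-occurrence texture of a late summed PET image.

The alternative quantification route: sum the late frames (default 40-60
min post-injection) into a single static volume, quantize the in-mask
intensities to Ng gray levels, accumulate one pooled gray-level
co-occurrence matrix (GLCM) over a set of 3D voxel displacements, and
reduce it to the 14 classical Haralick statistics.

Conventions (all configurable):

* offsets: the 13 unique distance-1 3D directions, pooled into a single
  GLCM before normalization;
* symmetric accumulation (each pair counted in both orders);
* pairs with either voxel outside the brain mask are discarded -- no
  padding, so the texture is strictly mask-aware;
* base-2 logarithms with the convention ``0 log 0 = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DynamicPETImage

__all__ = [
    "SummedImage",
    "QuantizedVolume",
    "GLCM",
    "HARALICK_FEATURE_NAMES",
    "DISTANCE_1_OFFSETS_3D",
    "sum_frames",
    "quantize",
    "compute_glcm",
    "haralick_features",
    "texture_pipeline",
]

logger = logging.getLogger(__name__)

#: The 13 unique 3D directions at Chebyshev distance 1 (one per +/- pair).
DISTANCE_1_OFFSETS_3D = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: Names of the 14 Haralick features, in canonical order.
HARALICK_FEATURE_NAMES = (
    "energy", "contrast", "correlation", "variance", "homogeneity",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
    "max_corr_coeff",
)

_LOG_EPS = 1e-12


@dataclass
class SummedImage:
    """Static volume: voxelwise sum of frames in a late time window."""

    data: np.ndarray
    window: tuple[float, float]   # (start, end) minutes post-injection


@dataclass
class QuantizedVolume:
    """Integer gray levels in ``[0, Ng - 1]`` inside the mask."""

    levels: np.ndarray            # int; values outside mask are undefined
    n_levels: int
    bounds: tuple[float, float]   # (low, high) used for scaling

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("Ng must be at least 2")


@dataclass
class GLCM:
    """Normalized gray-level co-occurrence distribution."""

    p: np.ndarray                 # (Ng, Ng), sums to 1
    offsets: tuple
    symmetric: bool
    pair_count: int

    def __post_init__(self) -> None:
        total = float(self.p.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"GLCM probabilities sum to {total}, not 1")
        if np.any(self.p < 0):
            raise ValueError("GLCM probabilities must be non-negative")


def sum_frames(img: DynamicPETImage, window_min: tuple[float, float],
               tol_s: float = 1.0) -> SummedImage:
    """Voxelwise sum of the frames lying inside a time window (minutes).

    A frame is included when its interval is contained in the window up to
    ``tol_s`` seconds; the window must align with frame boundaries and
    select at least one frame.
    """
    start_s, end_s = window_min[0] * 60.0, window_min[1] * 60.0
    sched = img.schedule
    if start_s < sched.start[0] - tol_s or end_s > sched.end[-1] + tol_s:
        raise ValueError("summation window exceeds the scan span")
    inside = (sched.start >= start_s - tol_s) & (sched.end <= end_s + tol_s)
    if not inside.any():
        raise ValueError("summation window selects no frames")
    covered = sched.duration[inside].sum()
    if abs(covered - (end_s - start_s)) > tol_s * max(int(inside.sum()), 1):
        raise ValueError("summation window does not align with frame boundaries")
    return SummedImage(img.data[..., inside].sum(axis=-1),
                       (window_min[0], window_min[1]))


def quantize(img: SummedImage, mask: np.ndarray, n_levels: int = 64,
             clip_percentiles: tuple[float, float] | None = None
             ) -> QuantizedVolume:
    """Linear min-max quantization of in-mask intensities to Ng levels.

    ``level = floor((x - low) / (high - low) * Ng)`` clamped to ``Ng - 1``;
    ``(low, high)`` are the in-mask extrema, or the given percentiles when
    ``clip_percentiles`` is set (values outside are clipped first).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if n_levels < 2:
        raise ValueError("Ng must be at least 2")
    vals = img.data[mask].astype(float)
    if clip_percentiles is not None:
        low, high = np.percentile(vals, clip_percentiles)
    else:
        low, high = float(vals.min()), float(vals.max())
    if high <= low:
        raise ValueError("constant image in mask: zero intensity range")
    scaled = np.clip((img.data - low) / (high - low), 0.0, 1.0)
    levels = np.minimum((scaled * n_levels).astype(np.int64), n_levels - 1)
    levels[~mask] = 0
    return QuantizedVolume(levels, n_levels, (low, high))


def compute_glcm(q: QuantizedVolume, mask: np.ndarray,
                 offsets=DISTANCE_1_OFFSETS_3D,
                 symmetric: bool = True) -> GLCM:
    """Accumulate one pooled GLCM over a set of voxel displacements.

    For each offset, every voxel pair with both members inside the mask
    contributes one count; counts are pooled across offsets, the transpose
    is added when ``symmetric``, and the matrix is normalized to sum to 1.
    """
    offsets = tuple(tuple(int(c) for c in o) for o in offsets)
    if not offsets:
        raise ValueError("at least one offset is required")
    mask = np.asarray(mask, dtype=bool)
    levels = q.levels
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    n_pairs = 0
    for off in offsets:
        src = tuple(slice(max(-d, 0), levels.shape[a] - max(d, 0))
                    for a, d in enumerate(off))
        dst = tuple(slice(max(d, 0), levels.shape[a] + min(d, 0))
                    for a, d in enumerate(off))
        valid = mask[src] & mask[dst]
        a = levels[src][valid]
        b = levels[dst][valid]
        np.add.at(counts, (a, b), 1)
        n_pairs += int(valid.sum())
    if n_pairs == 0:
        raise ValueError("no valid voxel pairs for any offset")
    counts_f = counts.astype(float)
    if symmetric:
        counts_f = counts_f + counts_f.T
    p = counts_f / counts_f.sum()
    return GLCM(p, offsets, symmetric, n_pairs)


def _entropy2(p: np.ndarray) -> float:
    """Base-2 Shannon entropy with 0 log 0 = 0."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def haralick_features(glcm: GLCM) -> dict:
    """The 14 classical Haralick statistics of a normalized GLCM.

    Returns an ordered dict keyed by :data:`HARALICK_FEATURE_NAMES`.  With a
    degenerate marginal (all mass on one level) correlation and the maximal
    correlation coefficient are undefined and reported as NaN.
    """
    p = glcm.p
    ng = p.shape[0]
    i = np.arange(ng, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sigma_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj

    energy = float((p ** 2).sum())
    contrast = float((diff ** 2 * p).sum())
    homogeneity = float((p / (1.0 + diff ** 2)).sum())
    entropy = _entropy2(p)

    # mean-referenced variance; the marginal mean is the standard reference
    variance = float(((ii - mu_x) ** 2 * p).sum())

    if sigma_x > 0 and sigma_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y)
                            / (sigma_x * sigma_y))
    else:
        logger.warning("degenerate GLCM marginal: correlation undefined")
        correlation = float("nan")

    # p_{x+y}: distribution of i + j, support 0 .. 2(Ng-1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int), p)
    k_sum = np.arange(2 * ng - 1, dtype=float)
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy2(p_sum)

    # p_{|x-y|}: distribution of |i - j|, support 0 .. Ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(diff).astype(int), p)
    k_diff = np.arange(ng, dtype=float)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = _entropy2(p_diff)

    # information measures of correlation
    hxy = entropy
    hx = _entropy2(px)
    hy = _entropy2(py)
    outer = np.outer(px, py)
    pos = p > 0
    hxy1 = float(-(p[pos] * np.log2(outer[pos] + _LOG_EPS)).sum())
    pos_o = outer > 0
    hxy2 = float(-(outer[pos_o] * np.log2(outer[pos_o])).sum())
    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    # maximal correlation coefficient: sqrt of the second-largest eigenvalue
    # of Q(i,j) = sum_k p(i,k) p(j,k) / (p_x(i) p_y(k))
    occupied = (px > 0) & (py > 0)
    if occupied.sum() >= 2 and sigma_x > 0 and sigma_y > 0:
        sub = p[np.ix_(occupied, occupied)]
        px_o = px[occupied]
        py_o = py[occupied]
        q = (sub / px_o[:, None]) @ (sub / py_o[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(np.clip(eig[1], 0.0, 1.0)))
    else:
        logger.warning("degenerate GLCM marginal: max_corr_coeff undefined")
        mcc = float("nan")

    values = (energy, contrast, correlation, variance, homogeneity,
              sum_average, sum_variance, sum_entropy, entropy,
              difference_variance, difference_entropy, imc1, imc2, mcc)
    return dict(zip(HARALICK_FEATURE_NAMES, values))


def texture_pipeline(img: DynamicPETImage, brain_mask: np.ndarray,
                     window_min: tuple[float, float] = (40.0, 60.0),
                     n_levels: int = 64,
                     offsets=DISTANCE_1_OFFSETS_3D,
                     symmetric: bool = True,
                     clip_percentiles: tuple[float, float] | None = None,
                     average_directions: bool = False) -> dict:
    """Late-frame summation -> quantization -> GLCM -> Haralick features.

    ``average_directions=True`` computes the 14 features per offset and
    averages them instead of pooling counts into one matrix.
    """
    summed = sum_frames(img, window_min)
    q = quantize(summed, brain_mask, n_levels, clip_percentiles)
    if average_directions:
        feats = [haralick_features(compute_glcm(q, brain_mask, (off,), symmetric))
                 for off in offsets]
        return {name: float(np.mean([f[name] for f in feats]))
                for name in HARALICK_FEATURE_NAMES}
    glcm = compute_glcm(q, brain_mask, offsets, symmetric)
    return haralick_features(glcm)
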