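"""Reference-region extraction and Logan graphical analysis.

The "classical" quantification route for a TSPO tracer with no anatomical
reference region:

1. supervised cluster analysis -- decompose every in-brain voxel's
   shape-normalized TAC against four predefined kinetic class curves by
   non-negative least squares and pool the voxels most dominated by the
   "grey matter without specific binding" class into a pseudo-reference
   region;
2. Logan reference-tissue graphical analysis -- regress the transformed
   integral coordinates over late frames; the slope is the distribution
   volume ratio (DVR), equal to 1 + BP under reference-tissue assumptions;
3. reduce the voxelwise DVR map to ROI means over a labelled atlas.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .core import TAC, DynamicPETImage
from .synthetic import KineticClassBasis

__all__ = [
    "ReferenceExtraction",
    "DVRImage",
    "nnls_shared_basis",
    "extract_reference_tac",
    "logan_dvr_tac",
    "logan_dvr_image",
    "suggest_t_star",
    "roi_means",
]

logger = logging.getLogger(__name__)

REFERENCE_CLASS = "gm_no_binding"


# ---------------------------------------------------------------------------
# non-negative least squares with a shared design matrix
# ---------------------------------------------------------------------------

def nnls_shared_basis(basis: np.ndarray, targets: np.ndarray,
                      tol: float = 1e-10) -> np.ndarray:
    """Exact NNLS solutions ``argmin_{w>=0} ||basis @ w - target||`` for many
    targets sharing one design matrix.

    With only a handful of columns (here four kinetic classes) the optimal
    active set can be found by enumerating all non-empty column subsets:
    for each subset solve the unconstrained least squares, then keep the
    subset whose solution is feasible (non-negative) and satisfies the KKT
    conditions (non-negative gradient on the excluded columns).  Because the
    design matrix is shared, each subset costs one matrix product over all
    targets, which makes the whole decomposition a few dense matmuls.

    Parameters
    ----------
    basis : (n_frames, n_classes) array
    targets : (n_targets, n_frames) array

    Returns
    -------
    (n_targets, n_classes) array of non-negative weights.
    """
    basis = np.asarray(basis, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n_frames, n_classes = basis.shape
    if targets.shape[1] != n_frames:
        raise ValueError("targets and basis disagree on the number of frames")
    if np.linalg.matrix_rank(basis) < n_classes:
        raise np.linalg.LinAlgError("collinear class TACs: singular basis")

    n = targets.shape[0]
    best_w = np.zeros((n, n_classes))
    best_obj = np.einsum("ij,ij->i", targets, targets)  # empty support
    # KKT for the empty support: gradient -basis^T y must be >= 0
    grad0 = -targets @ basis
    solved = np.all(grad0 >= -tol, axis=1)

    for size in range(1, n_classes + 1):
        for support in itertools.combinations(range(n_classes), size):
            cols = basis[:, support]
            # w_S = pinv(A_S) y for every target at once
            w_s = targets @ np.linalg.pinv(cols).T        # (n, |S|)
            feasible = np.all(w_s >= -tol, axis=1)
            resid = targets - w_s @ cols.T
            grad = -resid @ basis                          # (n, n_classes)
            excluded = [c for c in range(n_classes) if c not in support]
            kkt = np.all(grad[:, excluded] >= -tol, axis=1) if excluded \
                else np.ones(n, dtype=bool)
            obj = np.einsum("ij,ij->i", resid, resid)
            take = feasible & kkt & ~solved
            if take.any():
                w_full = np.zeros((take.sum(), n_classes))
                w_full[:, support] = np.maximum(w_s[take], 0.0)
                best_w[take] = w_full
                best_obj[take] = obj[take]
                solved |= take
        if solved.all():
            break

    if not solved.all():
        # numerically marginal voxels: fall back to the best feasible subset
        for i in np.where(~solved)[0]:
            from scipy.optimize import nnls as scipy_nnls
            best_w[i], _ = scipy_nnls(basis, targets[i])
    return best_w


# ---------------------------------------------------------------------------
# supervised cluster reference extraction
# ---------------------------------------------------------------------------

@dataclass
class ReferenceExtraction:
    """Result of supervised-cluster reference-region extraction."""

    reference_tac: TAC
    reference_mask: np.ndarray          # bool
    class_weight_maps: np.ndarray       # (4, nx, ny, nz), NaN outside brain
    class_names: tuple[str, ...]


def _tac_area(values: np.ndarray, mid_minutes: np.ndarray) -> np.ndarray:
    """Area under TAC(s) by trapezoid on frame midpoints, anchored at (0, 0)."""
    values = np.atleast_2d(values)
    t = np.concatenate([[0.0], mid_minutes])
    v = np.concatenate([np.zeros((values.shape[0], 1)), values], axis=1)
    return np.trapezoid(v, t, axis=1)


def extract_reference_tac(img: DynamicPETImage, brain_mask: np.ndarray,
                          basis: KineticClassBasis,
                          fraction: float = 0.1,
                          weight_threshold: float | None = None,
                          ) -> ReferenceExtraction:
    """Supervised cluster analysis: pseudo-reference region from class TACs.

    Every in-mask voxel TAC is normalized to unit area under the curve
    (shape, not amplitude), decomposed against the four area-normalized
    class TACs by non-negative least squares, and ranked by the weight of
    the grey-matter-without-specific-binding class.  The top ``fraction``
    of in-mask voxels (ties at the cutoff included, so the result does not
    depend on voxel ordering) form the reference mask; alternatively an
    absolute ``weight_threshold`` on that class weight can be used.  The
    reference TAC is the plain mean of the selected voxels' unnormalized
    TACs.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if basis.schedule.n_frames != img.schedule.n_frames:
        raise ValueError("basis and image schedules disagree")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("empty brain mask")

    mid_min = img.schedule.mid_minutes
    raw = img.data[brain_mask]                     # (n_vox, n_frames)
    areas = _tac_area(raw, mid_min)
    usable = areas > 0
    if not usable.any():
        raise ValueError("no voxel has positive TAC area; empty candidate set")
    norm = np.full_like(raw, np.nan)
    norm[usable] = raw[usable] / areas[usable, None]

    basis_area = _tac_area(basis.class_tacs, mid_min)
    if np.any(basis_area <= 0):
        raise ValueError("class TAC with non-positive area")
    basis_norm = (basis.class_tacs / basis_area[:, None]).T   # (frames, 4)

    weights = np.zeros((raw.shape[0], 4))
    weights[usable] = nnls_shared_basis(basis_norm, norm[usable])

    ref_idx = basis.class_names.index(REFERENCE_CLASS)
    ref_w = np.where(usable, weights[:, ref_idx], -np.inf)

    if weight_threshold is not None:
        selected = ref_w >= weight_threshold
    else:
        k = max(int(round(fraction * raw.shape[0])), 1)
        cutoff = np.sort(ref_w)[::-1][k - 1]
        selected = ref_w >= cutoff
    if not selected.any():
        raise ValueError("reference selection produced an empty mask")

    ref_mask = np.zeros(img.grid_shape, dtype=bool)
    ref_mask[brain_mask] = selected
    ref_tac = TAC(raw[selected].mean(axis=0), img.schedule)

    weight_maps = np.full((4,) + img.grid_shape, np.nan)
    for c in range(4):
        wmap = np.full(img.grid_shape, np.nan)
        wmap[brain_mask] = weights[:, c]
        weight_maps[c] = wmap

    return ReferenceExtraction(ref_tac, ref_mask, weight_maps,
                               tuple(basis.class_names))


# ---------------------------------------------------------------------------
# Logan graphical analysis
# ---------------------------------------------------------------------------

@dataclass
class DVRImage:
    """Voxelwise Logan DVR map with fit diagnostics."""

    data: np.ndarray            # DVR, NaN outside mask / failed fits
    t_star: float               # minutes
    intercept_map: np.ndarray
    fit_r2_map: np.ndarray
    n_failed: int = 0


def _cumint(values: np.ndarray, mid_minutes: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid integral at frame midpoints, anchored at (0, 0)."""
    values = np.atleast_2d(values)
    t = np.concatenate([[0.0], mid_minutes])
    v = np.concatenate([np.zeros((values.shape[0], 1)), values], axis=1)
    return cumulative_trapezoid(v, t, axis=1)[:, :]  # (n, n_frames)


def _logan_fit(target: np.ndarray, reference: np.ndarray,
               mid_minutes: np.ndarray, t_star: float):
    """Vectorized Logan regression for many target TACs, one reference.

    Returns (dvr, intercept, r2, ok) arrays; entries with non-positive
    target activity in the fit window or degenerate abscissa variance are
    flagged not-ok.
    """
    target = np.atleast_2d(target)
    late = mid_minutes >= t_star
    if late.sum() < 3:
        raise ValueError("fewer than 3 frames at or after t_star")
    int_t = _cumint(target, mid_minutes)[:, late]
    int_r = _cumint(reference, mid_minutes)[0, late]
    ct = target[:, late]

    ok = np.all(ct > 0, axis=1)
    ct_safe = np.where(ct > 0, ct, 1.0)
    y = int_t / ct_safe
    x = int_r[None, :] / ct_safe

    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=1)
    sxy = np.sum((x - xm) * (y - ym), axis=1)
    syy = np.sum((y - ym) ** 2, axis=1)
    ok &= sxx > 1e-12
    sxx_safe = np.where(sxx > 1e-12, sxx, 1.0)
    slope = sxy / sxx_safe
    intercept = (ym - slope[:, None] * xm)[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, sxy ** 2 / (sxx_safe * syy), 1.0)
    return slope, intercept, r2, ok


def logan_dvr_tac(target: TAC, reference: TAC, t_star: float = 20.0):
    """Logan reference-tissue fit of one TAC.

    Over frames with midpoint >= ``t_star`` minutes, regresses
    ``y(T) = int_0^T C_T / C_T(T)`` on ``x(T) = int_0^T C_ref / C_T(T)``;
    the slope is the DVR.  Returns ``(dvr, intercept, r2)``.
    """
    if target.schedule.n_frames != reference.schedule.n_frames:
        raise ValueError("target and reference must share a schedule")
    slope, intercept, r2, ok = _logan_fit(
        target.values, reference.values, target.schedule.mid_minutes, t_star)
    if not ok[0]:
        raise ValueError(
            "Logan fit undefined: non-positive target activity in the fit "
            "window or degenerate abscissa")
    return float(slope[0]), float(intercept[0]), float(r2[0])


def logan_dvr_image(img: DynamicPETImage, brain_mask: np.ndarray,
                    reference: TAC, t_star: float = 20.0) -> DVRImage:
    """Voxelwise Logan DVR over a brain mask.

    Voxels that fail the fit preconditions (non-positive late activity,
    flat abscissa) are set to NaN and counted.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("empty brain mask")
    slope, intercept, r2, ok = _logan_fit(
        img.data[brain_mask], reference.values,
        img.schedule.mid_minutes, t_star)
    n_failed = int((~ok).sum())
    if n_failed:
        logger.warning("Logan fit failed for %d/%d voxels (set to NaN)",
                       n_failed, ok.size)
    slope = np.where(ok, slope, np.nan)
    intercept = np.where(ok, intercept, np.nan)
    r2 = np.where(ok, r2, np.nan)

    def to_map(flat):
        out = np.full(img.grid_shape, np.nan)
        out[brain_mask] = flat
        return out

    return DVRImage(to_map(slope), t_star, to_map(intercept), to_map(r2),
                    n_failed=n_failed)


def suggest_t_star(target: TAC, reference: TAC, max_rel_dev: float = 0.10,
                   min_tail_frames: int = 4) -> float:
    """Automatic Logan linearization start.

    Fits the final ``min_tail_frames`` frames and returns the earliest frame
    midpoint (minutes) from which the maximum relative deviation of the
    Logan ordinate from that tail line stays below ``max_rel_dev``.
    """
    mid = target.schedule.mid_minutes
    int_t = _cumint(target.values, mid)[0]
    int_r = _cumint(reference.values, mid)[0]
    if np.any(target.values <= 0):
        raise ValueError("automatic t* requires strictly positive target TAC")
    y = int_t / target.values
    x = int_r / target.values
    tail = slice(len(mid) - min_tail_frames, len(mid))
    coef = np.polyfit(x[tail], y[tail], 1)
    pred = np.polyval(coef, x)
    rel_dev = np.abs(pred - y) / np.maximum(np.abs(y), 1e-12)
    for k in range(len(mid) - min_tail_frames + 1):
        if np.all(rel_dev[k:] < max_rel_dev):
            return float(mid[k])
    return float(mid[-min_tail_frames])


# ---------------------------------------------------------------------------
# ROI reduction
# ---------------------------------------------------------------------------

def roi_means(param_image: np.ndarray, atlas: np.ndarray,
              roi_names: dict) -> pd.DataFrame:
    """Mean of finite voxels of a parametric map per atlas label.

    Returns a DataFrame with columns ``roi, label, n_voxels, mean, sd``.
    Raises if a requested label is absent or has no finite voxel.
    """
    param_image = np.asarray(param_image, dtype=float)
    atlas = np.asarray(atlas)
    if param_image.shape != atlas.shape:
        raise ValueError("atlas not aligned with the parametric image")
    rows = []
    for label, name in roi_names.items():
        region = atlas == label
        if not region.any():
            raise ValueError(f"label {label} ({name}) absent from atlas")
        vals = param_image[region]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {name} has no finite voxels")
        rows.append({
            "roi": name,
            "label": label,
            "n_voxels": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        })
    return pd.DataFrame(rows)
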