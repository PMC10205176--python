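"""Synthetic dynamic-PET cohort generator.

Emulates a 60-min, 22-frame TSPO-tracer brain acquisition for a two-group
cohort (patients vs. healthy controls).  Each subject is a voxel grid whose
tissue is partitioned into four kinetic classes -- grey matter without
specific binding, white matter, blood, and grey matter with specific
binding -- the same class structure the supervised-cluster reference
extraction assumes.  Voxel time-activity curves are drawn from the
simplified reference tissue model (SRTM) so that every voxel has a known
ground-truth distribution volume ratio DVR = 1 + BP, which the Logan
analysis downstream should recover.

Group structure is injected twice, mirroring the two quantification routes
under study:

* a binding-potential elevation in a configurable subset of ROIs for the
  patient group (kinetic route: higher regional DVR);
* a spatially correlated multiplicative intensity field whose correlation
  length differs between groups (texture route: different co-occurrence
  statistics at identical mean uptake).

All randomness flows from explicit integer seeds; identical seeds give
bit-identical subjects.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import TAC, DynamicPETImage, FrameSchedule, make_frame_schedule

__all__ = [
    "KineticClassBasis",
    "PhantomConfig",
    "SyntheticSubject",
    "rise_washout_curve",
    "frame_average",
    "simulate_reference_tac",
    "simulate_target_tac",
    "make_class_basis",
    "generate_subject",
    "generate_cohort",
]

#: Canonical order of the four kinetic classes.
CLASS_NAMES = ("gm_no_binding", "white_matter", "blood", "gm_binding")

#: Atlas label -> ROI name for the default phantom layout.
DEFAULT_ROI_NAMES = {
    1: "superior_frontal_gyrus",
    2: "middle_frontal_gyrus",
    3: "superior_temporal_gyrus",
    4: "hippocampus",
    5: "precuneus",
    6: "inferior_parietal_lobule",
}


# ---------------------------------------------------------------------------
# analytic input curves and frame averaging
# ---------------------------------------------------------------------------

def rise_washout_curve(t_min, amplitude: float, rise_per_min: float = 2.0,
                       washout_per_min: float = 0.02):
    """Two-exponential bolus curve: fast mono-exponential rise, slow washout.

    ``C(t) = A' (exp(-washout t) - exp(-rise t))`` scaled so the peak equals
    ``amplitude`` (kBq/mL).  ``t_min`` is time in minutes; the curve is zero
    at injection and non-negative everywhere.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if rise_per_min <= washout_per_min:
        raise ValueError("rise rate must exceed washout rate")
    t = np.asarray(t_min, dtype=float)
    raw = np.exp(-washout_per_min * t) - np.exp(-rise_per_min * t)
    # analytic peak location/value of the difference of exponentials
    t_peak = np.log(rise_per_min / washout_per_min) / (rise_per_min - washout_per_min)
    peak = np.exp(-washout_per_min * t_peak) - np.exp(-rise_per_min * t_peak)
    out = amplitude * raw / peak
    return np.maximum(out, 0.0)


def frame_average(fn, schedule: FrameSchedule, dt_s: float = 1.0) -> np.ndarray:
    """Average an analytic curve ``fn(t_minutes)`` over each frame interval.

    Uses a dense uniform sub-grid (``dt_s`` seconds) with midpoint sampling,
    matching how a scanner frame integrates the continuous concentration.
    """
    values = np.empty(schedule.n_frames)
    for k in range(schedule.n_frames):
        n_sub = max(int(round(schedule.duration[k] / dt_s)), 1)
        edges = np.linspace(schedule.start[k], schedule.end[k], n_sub + 1)
        mids_min = (edges[:-1] + edges[1:]) / 2.0 / 60.0
        values[k] = float(np.mean(fn(mids_min)))
    return values


def simulate_reference_tac(schedule: FrameSchedule, amplitude: float = 30.0) -> TAC:
    """Reference-tissue TAC: frame averages of the rise-washout curve.

    The amplitude (peak kBq/mL) is arbitrary in absolute terms; no activity
    calibration is modelled.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    return TAC(frame_average(lambda t: rise_washout_curve(t, amplitude), schedule),
               schedule)


# ---------------------------------------------------------------------------
# SRTM forward model
# ---------------------------------------------------------------------------

def _exp_convolve(values: np.ndarray, theta: float, dt: float) -> np.ndarray:
    """``values (x) exp(-theta t)`` on a uniform grid (trapezoid recursion)."""
    decay = np.exp(-theta * dt)
    out = np.empty_like(values)
    out[0] = 0.0
    for n in range(1, values.size):
        out[n] = out[n - 1] * decay + 0.5 * dt * (values[n] + values[n - 1] * decay)
    return out


def _srtm_conv_term(ref_dense: np.ndarray, t_dense_min: np.ndarray,
                    k2: float, bp: float) -> np.ndarray:
    theta = k2 / (1.0 + bp)
    dt = t_dense_min[1] - t_dense_min[0]
    return _exp_convolve(ref_dense, theta, dt)


def simulate_target_tac(ref_tac: TAC, r1: float, k2: float, bp: float,
                        schedule: FrameSchedule | None = None,
                        dt_min: float = 0.05) -> TAC:
    """Forward-simulate a target-tissue TAC with the SRTM closed form.

    ``C_T(t) = R1 C_ref(t) + [k2 - R1 k2/(1+BP)] (C_ref (x) exp(-k2 t/(1+BP)))``

    The implied total distribution volume ratio is ``1 + BP``.  The reference
    curve is linearly interpolated from its frame midpoints onto a dense grid
    for the convolution; the R1-proportional term reuses the frame values
    directly (frame averaging is linear), so ``R1 = 1, BP = 0`` returns the
    reference exactly.
    """
    if k2 <= 0 or r1 <= 0:
        raise ValueError("R1 and k2 must be positive")
    if bp < 0:
        raise ValueError("BP must be non-negative")
    schedule = schedule or ref_tac.schedule
    if schedule.n_frames != ref_tac.schedule.n_frames:
        raise ValueError("schedule does not match the reference TAC")

    coef = k2 - r1 * k2 / (1.0 + bp)
    if coef == 0.0:
        return TAC(r1 * ref_tac.values, schedule)

    t_end = schedule.end[-1] / 60.0
    t_dense = np.arange(0.0, t_end + dt_min, dt_min)
    ref_dense = np.interp(
        t_dense,
        np.concatenate([[0.0], schedule.mid_minutes]),
        np.concatenate([[0.0], ref_tac.values]),
    )
    conv = _srtm_conv_term(ref_dense, t_dense, k2, bp)
    conv_frames = frame_average(
        lambda t: np.interp(t, t_dense, conv), schedule, dt_s=3.0
    )
    return TAC(r1 * ref_tac.values + coef * conv_frames, schedule)


# ---------------------------------------------------------------------------
# phantom configuration
# ---------------------------------------------------------------------------

@dataclass
class KineticClassBasis:
    """The four kinetic class TACs used by supervised-cluster extraction."""

    class_names: tuple[str, ...]
    class_tacs: np.ndarray  # (4, n_frames), kBq/mL
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.class_tacs = np.asarray(self.class_tacs, dtype=float)
        if len(self.class_names) != 4 or self.class_tacs.shape[0] != 4:
            raise ValueError("exactly four kinetic classes are required")
        if self.class_tacs.shape[1] != self.schedule.n_frames:
            raise ValueError("class TAC length must match the schedule")
        if np.any(self.class_tacs < 0):
            raise ValueError("class TACs must be non-negative")
        for i in range(4):
            for j in range(i + 1, 4):
                if np.allclose(self.class_tacs[i], self.class_tacs[j]):
                    raise ValueError("class TACs must be pairwise distinct")

    def tac(self, name: str) -> TAC:
        idx = self.class_names.index(name)
        return TAC(self.class_tacs[idx], self.schedule)


@dataclass
class PhantomConfig:
    """Parameters of the synthetic brain phantom and cohort.

    SRTM parameters per tissue class are ``(R1, k2 [1/min], BP)``.  The
    default grid (32 x 32 x 16, 2 mm voxels nominal) keeps a full 40-subject
    cohort tractable on one CPU while leaving enough voxels for stable
    co-occurrence statistics.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    amplitude: float = 30.0           # reference-curve peak, kBq/mL (nominal)
    srtm_params: dict = field(default_factory=lambda: {
        "gm_no_binding": (1.0, 0.35, 0.0),
        "white_matter": (0.5, 0.15, 0.10),
        "gm_binding": (0.95, 0.35, 0.25),
    })
    blood_amplitude_factor: float = 3.0   # blood peak relative to reference
    blood_washout_per_min: float = 0.35   # fast clearance
    blood_rise_per_min: float = 8.0       # sharp early peak
    noise_scale: float = 2.0          # kBq/mL * sqrt(s); sd = scale/sqrt(dur)
    texture_amplitude: float = 0.05   # sd of the multiplicative field
    texture_correlation_length: dict = field(
        default_factory=lambda: {"HC": 1.2, "AD": 1.6})  # smoothing sigma, voxels
    texture_length_jitter_sd: float = 0.25  # between-subject sigma variability
    bp_effect: float = 0.08           # AD binding elevation in target ROIs
    target_rois: tuple[str, ...] = ("superior_frontal_gyrus",)
    bp_jitter_sd: float = 0.06        # between-subject regional BP variability
    amplitude_jitter_sd: float = 0.05  # between-subject global scale variability

    def __post_init__(self) -> None:
        for name, (r1, k2, bp) in self.srtm_params.items():
            if r1 <= 0 or k2 <= 0 or bp < 0:
                raise ValueError(f"invalid SRTM parameters for class {name!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be non-negative")

    def noiseless(self) -> "PhantomConfig":
        """Copy with all stochastic ingredients switched off."""
        cfg = copy.deepcopy(self)
        cfg.noise_scale = 0.0
        cfg.texture_amplitude = 0.0
        cfg.bp_jitter_sd = 0.0
        cfg.amplitude_jitter_sd = 0.0
        cfg.texture_length_jitter_sd = 0.0
        return cfg


@dataclass
class SyntheticSubject:
    """One simulated subject: dynamic image plus ground truth."""

    subject_id: str
    label: str                      # "AD" or "HC"
    dynamic_image: DynamicPETImage
    brain_mask: np.ndarray          # bool, (nx, ny, nz)
    atlas: np.ndarray               # int labels, 0 = no ROI
    roi_names: dict
    class_map: np.ndarray           # int index into class_names, -1 outside
    class_names: tuple[str, ...]
    true_dvr: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        shape = self.dynamic_image.grid_shape
        for name in ("brain_mask", "atlas", "class_map", "true_dvr"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape does not match the image grid")
        if not self.brain_mask.any():
            raise ValueError("brain mask is empty")
        if np.any(self.true_dvr[self.brain_mask] < 0):
            raise ValueError("true DVR must be non-negative inside the mask")


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def default_phantom_layout(grid_shape):
    """Ellipsoidal brain with a white-matter core, a central blood pool,
    six grey-matter ROIs in octant sectors, and two reference sectors.

    Returns ``(brain_mask, class_map, atlas)`` where ``class_map`` indexes
    :data:`CLASS_NAMES` (-1 outside the brain) and ``atlas`` carries the ROI
    labels of :data:`DEFAULT_ROI_NAMES` (0 = no ROI).
    """
    nx, ny, nz = grid_shape
    if min(nx, ny, nz) < 8:
        raise ValueError("grid too small for the default layout")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = nx * 0.44, ny * 0.44, nz * 0.44
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    r = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2)
    brain_mask = r <= 1.0
    if not brain_mask.any():
        raise ValueError("degenerate layout: empty brain mask")

    class_map = np.full(grid_shape, -1, dtype=np.int8)
    atlas = np.zeros(grid_shape, dtype=np.int16)

    white = brain_mask & (r <= 0.55)
    gm = brain_mask & ~white

    # small central blood pool inside the white core
    dist_vox = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
    blood = dist_vox <= max(1.5, min(nx, ny, nz) / 12.0)
    blood &= brain_mask

    octant = ((x >= cx).astype(int) * 4 + (y >= cy).astype(int) * 2
              + (z >= cz).astype(int))

    class_map[gm] = CLASS_NAMES.index("gm_no_binding")
    for label in DEFAULT_ROI_NAMES:        # labels 1..6 -> octants 0..5
        roi = gm & (octant == label - 1)
        atlas[roi] = label
        class_map[roi] = CLASS_NAMES.index("gm_binding")
    class_map[white] = CLASS_NAMES.index("white_matter")
    class_map[blood] = CLASS_NAMES.index("blood")

    return brain_mask, class_map, atlas


# ---------------------------------------------------------------------------
# class TACs and subject synthesis
# ---------------------------------------------------------------------------

def _blood_curve_fn(config: PhantomConfig):
    return lambda t: rise_washout_curve(
        t,
        config.amplitude * config.blood_amplitude_factor,
        rise_per_min=config.blood_rise_per_min,
        washout_per_min=config.blood_washout_per_min,
    )


def make_class_basis(schedule: FrameSchedule,
                     config: PhantomConfig | None = None) -> KineticClassBasis:
    """Ground-truth TACs of the four kinetic classes under a phantom config."""
    config = config or PhantomConfig()
    ref = simulate_reference_tac(schedule, config.amplitude)
    tacs = np.empty((4, schedule.n_frames))
    for i, name in enumerate(CLASS_NAMES):
        if name == "blood":
            tacs[i] = frame_average(_blood_curve_fn(config), schedule)
        elif name == "gm_no_binding":
            tacs[i] = ref.values
        else:
            r1, k2, bp = config.srtm_params[name]
            tacs[i] = simulate_target_tac(ref, r1, k2, bp, schedule).values
    return KineticClassBasis(CLASS_NAMES, tacs, schedule)


def generate_subject(config: PhantomConfig, group: str, seed: int,
                     subject_id: str | None = None,
                     schedule: FrameSchedule | None = None) -> SyntheticSubject:
    """Simulate one subject of the given group ("AD" or "HC").

    Voxel TACs are the SRTM curve of the voxel's region plus zero-mean
    Gaussian noise with standard deviation ``noise_scale / sqrt(duration)``
    (the usual frame-duration weighting surrogate for reconstructed-PET
    noise), then scaled by a smooth multiplicative texture field whose
    correlation length depends on the group.  ``true_dvr`` stores the
    voxelwise ground truth ``1 + BP``.
    """
    if group not in ("AD", "HC"):
        raise ValueError("group must be 'AD' or 'HC'")
    schedule = schedule or make_frame_schedule()
    rng = np.random.default_rng(seed)
    brain_mask, class_map, atlas = default_phantom_layout(config.grid_shape)
    roi_by_name = {v: k for k, v in DEFAULT_ROI_NAMES.items()}

    ref = simulate_reference_tac(schedule, config.amplitude)

    # subject-level jitters (drawn even when sd = 0 to keep the stream layout
    # stable across configs)
    amp_factor = max(1.0 + config.amplitude_jitter_sd * rng.standard_normal(), 0.1)

    # per-region BP: class default, + per-ROI jitter, + group effect
    roi_bp = {}
    base_bp = config.srtm_params["gm_binding"][2]
    for label, name in DEFAULT_ROI_NAMES.items():
        bp = base_bp + config.bp_jitter_sd * rng.standard_normal()
        if group == "AD" and name in config.target_rois:
            bp += config.bp_effect
        roi_bp[label] = max(bp, 0.0)

    nx, ny, nz = config.grid_shape
    n_frames = schedule.n_frames
    data = np.zeros((nx, ny, nz, n_frames))
    true_dvr = np.zeros(config.grid_shape)
    true_dvr[brain_mask] = 1.0

    blood_tac = frame_average(_blood_curve_fn(config), schedule)

    def region_curve(class_name: str, bp_override=None) -> np.ndarray:
        if class_name == "blood":
            return blood_tac
        if class_name == "gm_no_binding":
            return ref.values
        r1, k2, bp = config.srtm_params[class_name]
        if bp_override is not None:
            bp = bp_override
        return simulate_target_tac(ref, r1, k2, bp, schedule).values

    # homogeneous classes
    for name in ("gm_no_binding", "white_matter", "blood"):
        idx = CLASS_NAMES.index(name)
        region = class_map == idx
        if not region.any():
            continue
        data[region] = region_curve(name)
        if name == "white_matter":
            true_dvr[region] = 1.0 + config.srtm_params[name][2]

    # binding grey matter, per ROI
    gm_binding_idx = CLASS_NAMES.index("gm_binding")
    for label in DEFAULT_ROI_NAMES:
        region = (class_map == gm_binding_idx) & (atlas == label)
        if not region.any():
            continue
        bp = roi_bp[label]
        data[region] = region_curve("gm_binding", bp_override=bp)
        true_dvr[region] = 1.0 + bp

    data *= amp_factor

    # group-dependent multiplicative texture field; the correlation length
    # carries between-subject variability around its group value
    field_noise = rng.standard_normal(config.grid_shape)
    sigma = config.texture_correlation_length[group] \
        + config.texture_length_jitter_sd * rng.standard_normal()
    sigma = max(sigma, 0.3)
    if config.texture_amplitude > 0:
        smooth = gaussian_filter(field_noise, sigma=sigma)
        smooth = (smooth - smooth[brain_mask].mean()) / smooth[brain_mask].std()
        tex = 1.0 + config.texture_amplitude * smooth
        tex = np.clip(tex, 0.05, None)
        data[brain_mask] *= tex[brain_mask][:, None]

    # frame-duration-weighted additive noise
    frame_noise = rng.standard_normal((int(brain_mask.sum()), n_frames))
    if config.noise_scale > 0:
        sd = config.noise_scale / np.sqrt(schedule.duration)
        data[brain_mask] += frame_noise * sd
        data[brain_mask] = np.maximum(data[brain_mask], 0.0)

    img = DynamicPETImage(data, schedule)
    if subject_id is None:
        subject_id = f"{group}-{seed}"
    return SyntheticSubject(
        subject_id=subject_id,
        label=group,
        dynamic_image=img,
        brain_mask=brain_mask,
        atlas=atlas,
        roi_names=dict(DEFAULT_ROI_NAMES),
        class_map=class_map,
        class_names=CLASS_NAMES,
        true_dvr=true_dvr,
        seed=seed,
    )


def generate_cohort(n_ad: int, n_hc: int, config: PhantomConfig | None = None,
                    seed: int = 0,
                    schedule: FrameSchedule | None = None) -> list[SyntheticSubject]:
    """Simulate a labelled cohort (default sizes: 19 patients, 21 controls).

    Per-subject seeds are derived from the master seed with a seed sequence,
    so the cohort is reproducible as a whole and each subject individually.
    """
    if n_ad < 1 or n_hc < 1:
        raise ValueError("cohort sizes must be at least 1 per group")
    config = config or PhantomConfig()
    schedule = schedule or make_frame_schedule()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_ad + n_hc)
    subjects = []
    for i in range(n_ad):
        sub_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
        subjects.append(generate_subject(
            config, "AD", sub_seed, subject_id=f"AD{i + 1:02d}",
            schedule=schedule))
    for j in range(n_hc):
        sub_seed = int(children[n_ad + j].generate_state(1)[0] % (2 ** 31))
        subjects.append(generate_subject(
            config, "HC", sub_seed, subject_id=f"HC{j + 1:02d}",
            schedule=schedule))
    return subjects
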