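"""Digital mouse-thorax phantom: CT, dynamic PET and study-design simulation.

The generator emulates the structure of a bleomycin (BLM) lung-fibrosis
imaging study: a body cylinder containing two ellipsoidal lungs; fibrotic
consolidations inserted as blobs until a target dense-band volume fraction
is reached; and a two-term lung tracer kinetic model

    C(t) = A_inj * [ A * exp(-alpha t)
                     + f_block * B_max * b * (1 - exp(-beta t))
                     + c0 ],

(decay-free, kBq/mL) where ``A`` is the perfusion amplitude washing out at
rate ``alpha``, the second term is saturable specific binding to the local
collagen burden ``b`` rising at rate ``beta``, ``f_block`` the fraction of
specific binding remaining under cold-peptide blocking, and ``c0`` an
optional constant offset (default 0, so the two-term form above is the
default model). The physically measured concentration is
``C(t) * 2**(-t / half_life)``.

Default kinetics are chosen so that the control (burden 0) curve washes out
to ~5% of its initial value by 12 min p.i. while a fibrotic curve plateaus —
the qualitative time-activity behaviour of a collagen-binding peptide
tracer — with absolute %ID/g values in the usual preclinical range. No
compartmental ODE model is claimed.

Ground-truth collagen burden is proportional to the local consolidation HU
excess, so "uptake tracks collagen content" holds by construction and is
testable against the CT-side segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .imaging_core import AcquisitionMeta, ROIMask, VolumeGrid

__all__ = [
    "PhantomConfig",
    "KineticParams",
    "GroundTruth",
    "TimepointData",
    "SubjectRecord",
    "StudyDesign",
    "build_thorax_ct",
    "lung_concentration",
    "measured_lung_concentration",
    "render_pet_series",
    "simulate_cohort",
    "dynamic_frame_schedule",
    "static_frame_schedule",
    "default_study_design",
    "pilot_tac_design",
    "DEFAULT_TRAJECTORIES",
]

#: Injected dose used throughout the emulated study: 5 MBq, 1.5 nmol.
DEFAULT_DOSE_MBQ = 5.0
DEFAULT_TRACER_NMOL = 1.5


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and tissue-appearance parameters of the digital thorax.

    HU distributions: aerated lung N(-650, 80), consolidation N(60, 60) —
    means inside the aerated (-800..-100) and dense (-100..300) HU bands.
    The PET grid must tile the CT grid by an integer factor per axis
    (volumes are rendered on the coarser PET grid by block averaging).
    """

    ct_shape: tuple[int, int, int] = (64, 64, 48)
    ct_spacing_mm: float = 0.4
    pet_shape: tuple[int, int, int] = (32, 32, 24)
    pet_spacing_mm: float = 0.8
    aerated_hu_mean: float = -650.0
    aerated_hu_sd: float = 80.0
    dense_hu_mean: float = 60.0
    dense_hu_sd: float = 60.0
    body_hu_mean: float = 40.0
    body_hu_sd: float = 20.0
    air_hu: float = -1000.0
    lesion_radius_mm: tuple[float, float] = (0.6, 2.0)
    ct_noise: bool = True
    sensitivity_cps_per_Bq: float = 0.05
    max_placement_attempts: int = 50_000

    def __post_init__(self) -> None:
        if not (-800.0 < self.aerated_hu_mean < -100.0):
            raise ValueError("aerated_hu_mean must lie in (-800, -100) HU")
        if not (-100.0 < self.dense_hu_mean < 300.0):
            raise ValueError("dense_hu_mean must lie in (-100, 300) HU")
        for c, p in zip(self.ct_shape, self.pet_shape):
            if c % p != 0:
                raise ValueError("pet_shape must divide ct_shape per axis")
        f = self.ct_shape[0] // self.pet_shape[0]
        if not math.isclose(self.pet_spacing_mm, self.ct_spacing_mm * f):
            raise ValueError("pet_spacing must equal ct_spacing * block factor")

    @property
    def block_factors(self) -> tuple[int, int, int]:
        return tuple(c // p for c, p in zip(self.ct_shape, self.pet_shape))  # type: ignore[return-value]

    @property
    def pet_origin(self) -> tuple[float, float, float]:
        # voxel-centre origin of the PET grid so both grids cover one extent
        return tuple(
            (f - 1) * self.ct_spacing_mm / 2.0 for f in self.block_factors
        )  # type: ignore[return-value]


@dataclass(frozen=True)
class KineticParams:
    """Two-term lung kinetic model parameters.

    Units: amplitudes in kBq/mL per MBq injected; rates in 1/min.
    ``blocking_factor`` is the fraction of specific binding remaining
    (1.0 = no blocking; 0.1 emulates a x100 cold-peptide excess).
    """

    perfusion_amplitude: float = 120.0
    washout_rate: float = 0.25
    binding_amplitude: float = 80.0
    binding_rate: float = 0.15
    baseline: float = 0.0
    blocking_factor: float = 1.0
    blood_pool_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.perfusion_amplitude <= 0 or self.washout_rate <= 0:
            raise ValueError("perfusion amplitude and washout rate must be > 0")
        if self.binding_rate <= 0:
            raise ValueError("binding rate must be > 0")
        if not 0.0 <= self.blocking_factor <= 1.0:
            raise ValueError("blocking_factor must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Known truth behind one rendered subject-timepoint.

    ``collagen_map`` (CT grid, arbitrary units, 0 outside lesions) stands in
    for histological collagen content; ``true_fibrosis_fraction`` is the
    achieved lesion-voxel fraction of the lung.
    """

    true_fibrosis_fraction: float
    collagen_map: np.ndarray | None
    mean_lung_burden: float


@dataclass
class TimepointData:
    day: int
    ct: VolumeGrid
    lung: ROIMask
    frames: list[VolumeGrid]
    meta: AcquisitionMeta
    ground_truth: GroundTruth
    kinetics: KineticParams | None = None
    biodistribution: "object | None" = None  # biodist.BiodistributionTable


@dataclass
class SubjectRecord:
    """One virtual animal across its imaging timepoints."""

    subject_id: str
    group: str
    timepoints: dict[int, TimepointData] = field(default_factory=dict)

    @property
    def days(self) -> list[int]:
        return sorted(self.timepoints)


#: Per-group fibrosis-fraction trajectories over days 0/8/15/22 emulating the
#: longitudinal design: controls stay clear; BLM progresses through the
#: fibrotic phase; treated groups share the BLM D8 state then regress under
#: daily nintedanib/tofacitinib; the blocking arm shares the BLM trajectory
#: (its effect is on PET binding, not CT).
DEFAULT_TRAJECTORIES: dict[str, dict[int, float]] = {
    "NaCl": {0: 0.0, 8: 0.0, 15: 0.0, 22: 0.0},
    "BLM": {0: 0.0, 8: 0.15, 15: 0.25, 22: 0.35},
    "BLM+nintedanib": {0: 0.0, 8: 0.15, 15: 0.10, 22: 0.08},
    "BLM+tofacitinib": {0: 0.0, 8: 0.15, 15: 0.13, 22: 0.08},
    "BLM+blocking": {0: 0.0, 8: 0.15, 15: 0.25, 22: 0.35},
}


@dataclass(frozen=True)
class StudyDesign:
    """Groups, sizes, schedule and effect trajectories of a simulated study."""

    groups: tuple[tuple[str, int], ...]
    timepoints: tuple[int, ...]
    trajectories: tuple[tuple[str, tuple[tuple[int, float], ...]], ...]
    frame_schedule: tuple[tuple[float, float], ...]
    burden_sd: float = 0.25
    blocking_factor: float = 0.1
    pet_noise: str = "poisson"
    with_biodistribution: bool = True

    def __post_init__(self) -> None:
        if any(n < 1 for _, n in self.groups):
            raise ValueError("group sizes must be >= 1")
        tps = self.timepoints
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        for _, traj in self.trajectories:
            for _, v in traj:
                if not 0.0 <= v <= 0.8:
                    raise ValueError("trajectory fractions must lie in [0, 0.8]")

    def trajectory(self, group: str) -> dict[int, float]:
        for g, traj in self.trajectories:
            if g == group:
                return dict(traj)
        raise KeyError(f"no trajectory for group {group!r}")


def static_frame_schedule(
    start: float = 15.0, end: float = 75.0, duration: float = 10.0
) -> tuple[tuple[float, float], ...]:
    """Contiguous frames covering the static quantification window."""
    starts = np.arange(start, end, duration)
    return tuple((float(s), float(duration)) for s in starts)


def dynamic_frame_schedule(
    start: float = 2.0, end: float = 75.0, interval: float = 2.0
) -> tuple[tuple[float, float], ...]:
    """The dynamic acquisition: 2-min frames from 2 to 75 min p.i.

    Yields 37 frames starting at 2, 4, ..., 74 min with mid-times
    3, 5, ..., 75 min.
    """
    starts = np.arange(start, end, interval)
    return tuple((float(s), float(interval)) for s in starts)


def default_study_design(
    n_per_group: int = 4,
    groups: tuple[str, ...] | None = None,
    timepoints: tuple[int, ...] = (0, 8, 15, 22),
    frame_schedule: tuple[tuple[float, float], ...] | None = None,
    **kwargs,
) -> StudyDesign:
    """The emulated longitudinal design: five arms, imaging at D0/D8/D15/D22,
    static 15-75 min acquisitions, n=4 per arm by default."""
    names = groups or tuple(DEFAULT_TRAJECTORIES)
    return StudyDesign(
        groups=tuple((g, n_per_group) for g in names),
        timepoints=timepoints,
        trajectories=tuple(
            (g, tuple(sorted(DEFAULT_TRAJECTORIES[g].items()))) for g in names
        ),
        frame_schedule=frame_schedule or static_frame_schedule(),
        **kwargs,
    )


def pilot_tac_design(
    n_control: int = 20, n_blm: int = 20, **kwargs
) -> StudyDesign:
    """The dynamic pilot: controls vs established fibrosis (D21 analogue)
    imaged with 2-min frames from 2 to 75 min p.i."""
    return StudyDesign(
        groups=(("NaCl", n_control), ("BLM", n_blm)),
        timepoints=(21,),
        trajectories=(
            ("NaCl", ((21, 0.0),)),
            ("BLM", ((21, 0.35),)),
        ),
        frame_schedule=dynamic_frame_schedule(),
        with_biodistribution=False,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Thorax geometry and CT rendering
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _thorax_geometry(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """(body_mask, lung_mask) boolean arrays on the CT grid (cached)."""
    nx, ny, nz = config.ct_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    body = ((ii - cx) ** 2 + (jj - cy) ** 2) <= (0.45 * min(nx, ny)) ** 2
    lung = np.zeros(config.ct_shape, dtype=bool)
    semi = (0.16 * nx, 0.28 * ny, 0.38 * nz)
    for xfrac in (0.30, 0.70):
        lx, ly, lz = xfrac * (nx - 1), (ny - 1) / 2.0, (nz - 1) / 2.0
        lung |= (
            ((ii - lx) / semi[0]) ** 2
            + ((jj - ly) / semi[1]) ** 2
            + ((kk - lz) / semi[2]) ** 2
        ) <= 1.0
    lung &= body
    return body, lung


def _sphere_offsets(radius_vox: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r = int(math.ceil(radius_vox))
    ax = np.arange(-r, r + 1)
    di, dj, dk = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = di**2 + dj**2 + dk**2 <= radius_vox**2
    return di[keep], dj[keep], dk[keep]


def build_thorax_ct(
    config: PhantomConfig,
    burden: float,
    seed: int,
) -> tuple[VolumeGrid, ROIMask, GroundTruth]:
    """Render one thorax CT with a target fibrosis fraction.

    Consolidation blobs are placed at random lung sites — coarse spheres
    first, then ever finer ones — until the lesion-voxel fraction of the
    lung reaches ``burden`` (achieved fraction always within +-0.02 of the
    target; typically within a few 1e-4). With ``config.ct_noise`` each
    tissue class draws per-voxel HU from its normal distribution, otherwise
    class means are used (noise-free render).

    The collagen burden map is proportional to the lesion HU excess above
    -100 HU, normalised so the expected lesion burden is 1.0; it is zero in
    aerated tissue.
    """
    if not 0.0 <= burden <= 0.8:
        raise ValueError("burden must lie in [0, 0.8]")
    rng = np.random.default_rng(seed)
    body, lung = _thorax_geometry(config)
    lung_idx = np.argwhere(lung)
    n_lung = len(lung_idx)

    lesion = np.zeros(config.ct_shape, dtype=bool)
    achieved = 0.0
    r_min_vox = max(1.0, config.lesion_radius_mm[0] / config.ct_spacing_mm)
    r_max_vox = config.lesion_radius_mm[1] / config.ct_spacing_mm
    attempts = 0
    while achieved < burden - 1e-9:
        attempts += 1
        if attempts > config.max_placement_attempts:
            raise RuntimeError(
                f"unreachable fibrosis target {burden} after "
                f"{config.max_placement_attempts} placement attempts"
            )
        gap = burden - achieved
        r_fit = (gap * n_lung * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        r = float(np.clip(r_fit, 1.0, r_max_vox))
        if gap > 0.02:
            r = max(r, r_min_vox)
        ci, cj, ck = lung_idx[rng.integers(n_lung)]
        di, dj, dk = _sphere_offsets(r)
        pi, pj, pk = ci + di, cj + dj, ck + dk
        ok = (
            (pi >= 0) & (pi < config.ct_shape[0])
            & (pj >= 0) & (pj < config.ct_shape[1])
            & (pk >= 0) & (pk < config.ct_shape[2])
        )
        pi, pj, pk = pi[ok], pj[ok], pk[ok]
        inside = lung[pi, pj, pk] & ~lesion[pi, pj, pk]
        lesion[pi[inside], pj[inside], pk[inside]] = True
        achieved += int(inside.sum()) / n_lung

    hu = np.full(config.ct_shape, config.air_hu, dtype=np.float64)
    aerated = lung & ~lesion
    shell = body & ~lung
    if config.ct_noise:
        hu[shell] = rng.normal(config.body_hu_mean, config.body_hu_sd, shell.sum())
        hu[aerated] = rng.normal(
            config.aerated_hu_mean, config.aerated_hu_sd, aerated.sum()
        )
        hu[lesion] = rng.normal(
            config.dense_hu_mean, config.dense_hu_sd, lesion.sum()
        )
    else:
        hu[shell] = config.body_hu_mean
        hu[aerated] = config.aerated_hu_mean
        hu[lesion] = config.dense_hu_mean
    np.clip(hu, -1024.0, 3071.0, out=hu)

    collagen = np.zeros(config.ct_shape, dtype=np.float64)
    norm = config.dense_hu_mean + 100.0
    collagen[lesion] = np.maximum(hu[lesion] + 100.0, 0.0) / norm

    spacing = (config.ct_spacing_mm,) * 3
    ct = VolumeGrid(values=hu, spacing=spacing, modality="CT")
    mask = ROIMask(lung, label="lung")
    truth = GroundTruth(
        true_fibrosis_fraction=float(achieved),
        collagen_map=collagen,
        mean_lung_burden=float(collagen[lung].mean()),
    )
    return ct, mask, truth


# ---------------------------------------------------------------------------
# Kinetics and PET rendering
# ---------------------------------------------------------------------------

def lung_concentration(
    t_min,
    kinetics: KineticParams,
    burden: float,
    meta: AcquisitionMeta,
):
    """Decay-free lung activity concentration C(t) in kBq/mL (see module
    docstring for the closed form). Accepts scalar or array times."""
    t = np.asarray(t_min, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("negative time")
    k = kinetics
    c = meta.injected_activity_MBq * (
        k.perfusion_amplitude * np.exp(-k.washout_rate * t)
        + k.blocking_factor
        * k.binding_amplitude
        * burden
        * (1.0 - np.exp(-k.binding_rate * t))
        + k.baseline
    )
    return float(c) if np.isscalar(t_min) else c


def measured_lung_concentration(
    t_min, kinetics: KineticParams, burden: float, meta: AcquisitionMeta
):
    """Physically measured (decayed) concentration:
    ``C(t) * 2**(-t/half_life)``."""
    t = np.asarray(t_min, dtype=np.float64)
    return lung_concentration(t_min, kinetics, burden, meta) * 2.0 ** (
        -t / meta.half_life_min
    )


def _exp_frame_mean(k: float, t0: float, t1: float) -> float:
    """Frame average of exp(-k t) over [t0, t1]."""
    if k < 1e-12:
        return 1.0
    return (math.exp(-k * t0) - math.exp(-k * t1)) / (k * (t1 - t0))


def frame_mean_coefficients(
    kinetics: KineticParams,
    meta: AcquisitionMeta,
    frame: tuple[float, float],
    decayed: bool = True,
) -> tuple[float, float, float]:
    """Per-frame scalars (a, s, blood) such that the frame-averaged
    concentration of a lung voxel with burden b is ``a + s*b`` and of a body
    (blood-pool) voxel is ``blood``."""
    t0, t1 = frame[0], frame[0] + frame[1]
    lam = math.log(2.0) / meta.half_life_min if decayed else 0.0
    k = kinetics
    d = meta.injected_activity_MBq
    e_wash = _exp_frame_mean(k.washout_rate + lam, t0, t1)
    e_flat = _exp_frame_mean(lam, t0, t1)
    e_bind = _exp_frame_mean(k.binding_rate + lam, t0, t1)
    a = d * (k.perfusion_amplitude * e_wash + k.baseline * e_flat)
    s = d * k.blocking_factor * k.binding_amplitude * (e_flat - e_bind)
    blood = d * k.blood_pool_fraction * k.perfusion_amplitude * e_wash
    return a, s, blood


def _block_average(arr: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    f0, f1, f2 = factors
    n0, n1, n2 = arr.shape
    return (
        arr.reshape(n0 // f0, f0, n1 // f1, f1, n2 // f2, f2)
        .mean(axis=(1, 3, 5))
    )


def _validate_schedule(frame_schedule) -> None:
    if len(frame_schedule) == 0:
        raise ValueError("empty frame schedule")
    prev_end = -math.inf
    prev_start = -math.inf
    for start, dur in frame_schedule:
        if dur <= 0 or start < 0:
            raise ValueError("frame start must be >= 0 and duration > 0")
        if start <= prev_start:
            raise ValueError("frame starts must be strictly increasing")
        if start < prev_end - 1e-9:
            raise ValueError("overlapping frames")
        prev_start, prev_end = start, start + dur


def render_pet_series(
    ct_truth: GroundTruth,
    lung: ROIMask,
    kinetics: KineticParams,
    meta: AcquisitionMeta,
    frame_schedule,
    config: PhantomConfig,
    noise: str = "poisson",
    seed: int = 0,
) -> list[VolumeGrid]:
    """Render the dynamic PET frame list on the PET grid.

    Each frame voxel holds the frame-averaged *measured* (decayed)
    concentration for the voxel's collagen burden; the body shell carries a
    blood-pool curve scaled from the perfusion amplitude. With
    ``noise="poisson"``, expected counts per voxel
    (Bq * mL * sensitivity * seconds) are Poisson-sampled and converted
    back to concentration.
    """
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    if ct_truth.collagen_map is None:
        raise ValueError("ground truth carries no collagen map")
    _validate_schedule(frame_schedule)
    rng = np.random.default_rng(seed)
    factors = config.block_factors
    body, _ = _thorax_geometry(config)

    lung_frac = _block_average(lung.membership.astype(np.float64), factors)
    body_frac = _block_average(body.astype(np.float64), factors)
    burden_blk = _block_average(ct_truth.collagen_map, factors)
    with np.errstate(invalid="ignore"):
        burden_eff = np.where(lung_frac > 0, burden_blk / np.maximum(lung_frac, 1e-12), 0.0)
    lung_pet = lung_frac >= 0.5
    body_pet = (body_frac >= 0.5) & ~lung_pet

    spacing = (config.pet_spacing_mm,) * 3
    vox_mL = config.pet_spacing_mm**3 / 1000.0
    frames: list[VolumeGrid] = []
    for start, dur in frame_schedule:
        a, s, blood = frame_mean_coefficients(kinetics, meta, (start, dur))
        vals = np.zeros(config.pet_shape, dtype=np.float64)
        vals[lung_pet] = a + s * burden_eff[lung_pet]
        vals[body_pet] = blood
        if noise == "poisson":
            scale = 1000.0 * vox_mL * config.sensitivity_cps_per_Bq * dur * 60.0
            counts = rng.poisson(vals * scale)
            vals = counts / scale
        frames.append(
            VolumeGrid(
                values=vals,
                spacing=spacing,
                origin=config.pet_origin,
                modality="PET",
                frame_start_min=float(start),
                frame_duration_min=float(dur),
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _subject_seed(seed: int, *key: int) -> list[int]:
    return [int(seed), *[int(k) for k in key]]


def simulate_cohort(
    design: StudyDesign,
    config: PhantomConfig | None = None,
    kinetics: KineticParams | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Simulate every subject of a study design.

    Each subject draws a lognormal severity multiplier (median 1, sigma
    ``design.burden_sd``) applied to its whole group trajectory, so
    inter-animal variability is shared across timepoints — severe animals
    at D8 stay severe at D22. The blocking arm keeps the BLM trajectory but
    renders PET with ``blocking_factor`` on the specific-binding term.
    Bit-identical for identical (design, config, kinetics, seed).
    """
    config = config or PhantomConfig()
    kinetics = kinetics or KineticParams()
    from . import biodist  # local import: biodist consumes phantom types

    records: list[SubjectRecord] = []
    for gi, (group, n) in enumerate(design.groups):
        traj = design.trajectory(group)
        gk = kinetics
        if "blocking" in group.lower():
            gk = replace(kinetics, blocking_factor=design.blocking_factor)
        for si in range(n):
            subj_rng = np.random.default_rng(_subject_seed(seed, gi, si))
            mult = float(subj_rng.lognormal(mean=0.0, sigma=design.burden_sd))
            rec = SubjectRecord(subject_id=f"{group}-{si + 1:02d}", group=group)
            for ti, day in enumerate(design.timepoints):
                target = float(np.clip(traj[day] * mult, 0.0, 0.8))
                ct_seed = _subject_seed(seed, gi, si, ti, 1)
                pet_seed = _subject_seed(seed, gi, si, ti, 2)
                bio_seed = _subject_seed(seed, gi, si, ti, 3)
                ct, lung_mask, truth = build_thorax_ct(
                    config, target, ct_seed  # type: ignore[arg-type]
                )
                meta = AcquisitionMeta(
                    injected_activity_MBq=DEFAULT_DOSE_MBQ,
                    tracer_amount_nmol=DEFAULT_TRACER_NMOL,
                )
                frames = render_pet_series(
                    truth,
                    lung_mask,
                    gk,
                    meta,
                    design.frame_schedule,
                    config,
                    noise=design.pet_noise,
                    seed=pet_seed,  # type: ignore[arg-type]
                )
                tp = TimepointData(
                    day=day,
                    ct=ct,
                    lung=lung_mask,
                    frames=frames,
                    meta=meta,
                    ground_truth=truth,
                    kinetics=gk,
                )
                if design.with_biodistribution:
                    tp.biodistribution = biodist.synthesize_biodistribution(
                        rec.subject_id, group, day, truth, gk, meta,
                        seed=bio_seed,  # type: ignore[arg-type]
                    )
                rec.timepoints[day] = tp
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Cohort disk layout (CLI): NIfTI volumes + CSV tables + manifest.json
# ---------------------------------------------------------------------------

def save_cohort(records: list[SubjectRecord], out_dir) -> None:
    """Write a cohort as per-subject NIfTI volumes, ``ground_truth.csv``,
    ``biodistribution.csv`` and a ``manifest.json`` index."""
    import json as _json
    from pathlib import Path

    import pandas as pd

    from .imaging_core import write_mask, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": []}
    truth_rows = []
    bio_tables = []
    for rec in records:
        entry = {"subject_id": rec.subject_id, "group": rec.group, "timepoints": []}
        for day in rec.days:
            tp = rec.timepoints[day]
            tp_dir = out / rec.subject_id / f"d{day:02d}"
            tp_dir.mkdir(parents=True, exist_ok=True)
            write_volume(tp.ct, tp_dir / "ct.nii.gz")
            write_mask(tp.lung, tp.ct, tp_dir / "lung.nii.gz")
            frame_files = []
            for i, fr in enumerate(tp.frames):
                name = f"frame_{i:03d}.nii.gz"
                write_volume(fr, tp_dir / name)
                frame_files.append(str(Path(rec.subject_id) / f"d{day:02d}" / name))
            entry["timepoints"].append(
                {
                    "day": day,
                    "ct": str(Path(rec.subject_id) / f"d{day:02d}" / "ct.nii.gz"),
                    "lung": str(Path(rec.subject_id) / f"d{day:02d}" / "lung.nii.gz"),
                    "frames": frame_files,
                    "meta": {
                        "injected_activity_MBq": tp.meta.injected_activity_MBq,
                        "half_life_min": tp.meta.half_life_min,
                        "tracer_amount_nmol": tp.meta.tracer_amount_nmol,
                    },
                }
            )
            truth_rows.append(
                dict(
                    subject_id=rec.subject_id,
                    group=rec.group,
                    day=day,
                    true_fibrosis_fraction=tp.ground_truth.true_fibrosis_fraction,
                    mean_lung_burden=tp.ground_truth.mean_lung_burden,
                )
            )
            if tp.biodistribution is not None:
                bio_tables.append(tp.biodistribution)
        manifest["subjects"].append(entry)
    (out / "manifest.json").write_text(_json.dumps(manifest, indent=1))
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    if bio_tables:
        from .biodist import tables_to_frame

        tables_to_frame(bio_tables).to_csv(out / "biodistribution.csv", index=False)


def load_cohort(cohort_dir) -> list[SubjectRecord]:
    """Read a cohort written by :func:`save_cohort` back into records.

    Ground truth reloads without the voxelwise collagen map (scalar truth
    only); biodistribution tables reload from ``biodistribution.csv``.
    """
    import json as _json
    from pathlib import Path

    import pandas as pd

    from .imaging_core import read_mask, read_volume

    root = Path(cohort_dir)
    manifest = _json.loads((root / "manifest.json").read_text())
    truth = pd.read_csv(root / "ground_truth.csv").set_index(["subject_id", "day"])
    bio_path = root / "biodistribution.csv"
    bio = None
    if bio_path.exists():
        from .biodist import frame_to_tables

        bio = frame_to_tables(pd.read_csv(bio_path))
    records = []
    for sub in manifest["subjects"]:
        rec = SubjectRecord(subject_id=sub["subject_id"], group=sub["group"])
        for tp in sub["timepoints"]:
            day = int(tp["day"])
            trow = truth.loc[(sub["subject_id"], day)]
            gt = GroundTruth(
                true_fibrosis_fraction=float(trow["true_fibrosis_fraction"]),
                collagen_map=None,
                mean_lung_burden=float(trow["mean_lung_burden"]),
            )
            meta = AcquisitionMeta(
                injected_activity_MBq=float(tp["meta"]["injected_activity_MBq"]),
                half_life_min=float(tp["meta"]["half_life_min"]),
                tracer_amount_nmol=tp["meta"].get("tracer_amount_nmol"),
            )
            rec.timepoints[day] = TimepointData(
                day=day,
                ct=read_volume(root / tp["ct"]),
                lung=read_mask(root / tp["lung"], label="lung"),
                frames=[read_volume(root / f) for f in tp["frames"]],
                meta=meta,
                ground_truth=gt,
                biodistribution=(bio or {}).get((sub["subject_id"], day)),
            )
        records.append(rec)
    return records
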