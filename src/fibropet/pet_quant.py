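"""PET-side quantification: decay correction, %ID/g, compartment uptake, TACs.

Uptake is expressed as percent injected dose per gram of tissue,

    %ID/g = 100 * A_ROI / (A_injected * m_ROI),

with the ROI activity decay-corrected to injection time. Because %ID/g is
intensive, it reduces to ``100 * c_corr / (A_injected * rho)`` where
``c_corr`` is the mean corrected concentration (kBq/mL), ``A_injected`` the
dose in kBq and ``rho`` the tissue mass density (g/mL, default 1.0).

Conventions (documented, both standard in preclinical PET):

* decay reference time = injection time; the frame mid-time is the time
  coordinate and the decay-correction point of each frame;
* static window uptake = frame-duration-weighted mean over frames whose
  mid-time falls in the window (default 15-75 min p.i.); an ``endpoint``
  mode (last in-window frame) is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ct_quant import DensitySegmentation
from .imaging_core import AcquisitionMeta, ROIMask, VolumeGrid, resample_mask

__all__ = [
    "TimeActivityCurve",
    "UptakeResult",
    "decay_factor",
    "percent_id_per_gram",
    "compartment_uptake",
    "build_tac",
    "window_uptake",
    "tac_divergence",
    "median_tac",
]

#: Static quantification window in minutes p.i.
DEFAULT_WINDOW = (15.0, 75.0)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Decay-corrected ROI uptake across dynamic frames.

    ``mid_times_min`` are frame mid-times in minutes p.i. (strictly
    increasing); ``uptake_pct_id_g`` the matching %ID/g values.
    """

    mid_times_min: tuple[float, ...]
    uptake_pct_id_g: tuple[float, ...]
    decay_corrected: bool = True
    roi_label: str = "lung"

    def __post_init__(self) -> None:
        if len(self.mid_times_min) != len(self.uptake_pct_id_g):
            raise ValueError("times and uptakes must have equal length")
        t = np.asarray(self.mid_times_min)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("mid-times must be strictly increasing")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.mid_times_min, self.uptake_pct_id_g))


@dataclass(frozen=True)
class UptakeResult:
    """%ID/g over the whole lung and its density compartments.

    ``dense_pct_id_g`` is ``None`` when the dense compartment is empty
    (no fibrotic tissue) — distinct from zero signal.
    """

    whole_lung_pct_id_g: float
    aerated_pct_id_g: float | None
    dense_pct_id_g: float | None
    window_min: tuple[float, float]
    decay_corrected: bool
    tissue_density_g_mL: float


def decay_factor(elapsed_min: float, half_life_min: float) -> float:
    """Decay-correction multiplier referencing activity back in time.

    ``corrected = measured * 2**(elapsed/half_life)``; multiplicative in
    elapsed time and strictly increasing.
    """
    if half_life_min <= 0:
        raise ValueError("half_life_min must be > 0")
    if elapsed_min < 0:
        raise ValueError("negative elapsed time")
    return float(2.0 ** (elapsed_min / half_life_min))


def percent_id_per_gram(
    pet: VolumeGrid,
    mask: ROIMask,
    meta: AcquisitionMeta,
    density_g_per_mL: float = 1.0,
    decay_correct: bool = True,
) -> float:
    """ROI %ID/g of one PET frame, decay-corrected to injection time."""
    if pet.modality != "PET":
        raise ValueError(f"modality mismatch: expected PET, got {pet.modality}")
    if mask.membership.shape != pet.values.shape:
        raise ValueError("mask not congruent with PET grid")
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    if density_g_per_mL <= 0:
        raise ValueError("density must be > 0")
    mean_conc = float(pet.values[mask.membership].mean())  # kBq/mL, measured
    if decay_correct:
        mean_conc *= decay_factor(pet.frame_mid_min, meta.half_life_min)
    injected_kBq = meta.injected_activity_MBq * 1000.0
    return 100.0 * mean_conc / (injected_kBq * density_g_per_mL)


def compartment_uptake(
    pet: VolumeGrid,
    seg: DensitySegmentation,
    meta: AcquisitionMeta,
    density_g_per_mL: float = 1.0,
    decay_correct: bool = True,
) -> UptakeResult:
    """%ID/g separately over aerated and dense CT compartments plus whole lung.

    CT-derived masks are carried onto the PET grid by nearest-neighbour
    resampling when the grids differ.
    """
    masks = {}
    for m in (seg.lung, seg.aerated, seg.dense):
        if m.membership.shape != pet.values.shape:
            masks[m.label] = resample_mask(m, seg.source, pet)
        else:
            masks[m.label] = m

    def _u(m: ROIMask) -> float | None:
        if m.voxel_count == 0:
            return None
        return percent_id_per_gram(pet, m, meta, density_g_per_mL, decay_correct)

    whole = _u(masks["lung"])
    if whole is None:
        raise ValueError("empty lung mask on PET grid")
    start = pet.frame_start_min if pet.frame_start_min is not None else 0.0
    dur = pet.frame_duration_min if pet.frame_duration_min is not None else 0.0
    return UptakeResult(
        whole_lung_pct_id_g=whole,
        aerated_pct_id_g=_u(masks["aerated"]),
        dense_pct_id_g=_u(masks["dense"]),
        window_min=(start, start + dur),
        decay_corrected=decay_correct,
        tissue_density_g_mL=density_g_per_mL,
    )


def _check_frames(frames: list[VolumeGrid]) -> None:
    if len(frames) < 1:
        raise ValueError("no frames")
    starts, ends = [], []
    for fr in frames:
        if fr.frame_start_min is None or fr.frame_duration_min is None:
            raise ValueError("missing frame timing")
        starts.append(fr.frame_start_min)
        ends.append(fr.frame_start_min + fr.frame_duration_min)
    for i in range(1, len(frames)):
        if starts[i] <= starts[i - 1]:
            raise ValueError("frames must be strictly increasing")
        if starts[i] < ends[i - 1] - 1e-9:
            raise ValueError("overlapping frames")


def build_tac(
    frames: list[VolumeGrid],
    mask: ROIMask,
    meta: AcquisitionMeta,
    density_g_per_mL: float = 1.0,
    decay_correct: bool = True,
    roi_label: str = "lung",
) -> TimeActivityCurve:
    """Time-activity curve: one %ID/g point per frame at the frame mid-time."""
    if len(frames) < 2:
        raise ValueError("at least two frames required for a TAC")
    _check_frames(frames)
    mids = [fr.frame_mid_min for fr in frames]
    ups = [
        percent_id_per_gram(fr, mask, meta, density_g_per_mL, decay_correct)
        for fr in frames
    ]
    return TimeActivityCurve(
        mid_times_min=tuple(mids),
        uptake_pct_id_g=tuple(ups),
        decay_corrected=decay_correct,
        roi_label=roi_label,
    )


def window_uptake(
    frames: list[VolumeGrid],
    mask: ROIMask,
    meta: AcquisitionMeta,
    seg: DensitySegmentation | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    density_g_per_mL: float = 1.0,
    mode: str = "mean",
) -> UptakeResult:
    """Static uptake over the quantification window.

    Frame-duration-weighted mean of per-frame %ID/g over frames whose
    mid-time lies in ``[window[0], window[1]]`` (``mode="mean"``, default),
    or the last in-window frame (``mode="endpoint"``).
    """
    if window[0] >= window[1]:
        raise ValueError("window start must be < end")
    _check_frames(frames)
    sel = [
        fr for fr in frames if window[0] <= fr.frame_mid_min <= window[1]
    ]
    if not sel:
        raise ValueError("no frames in window")
    if mode == "endpoint":
        sel = [sel[-1]]
    elif mode != "mean":
        raise ValueError(f"unknown mode {mode!r}")
    weights = np.array([fr.frame_duration_min for fr in sel], dtype=float)
    weights /= weights.sum()

    ref = sel[0]
    if any(fr.values.shape != ref.values.shape for fr in sel):
        raise ValueError("frames must share one grid")

    def _weighted(m: ROIMask, src: VolumeGrid | None) -> float | None:
        if m.membership.shape != ref.values.shape:
            if src is None:
                raise ValueError("mask not congruent and no source grid")
            m = resample_mask(m, src, ref)
        if m.voxel_count == 0:
            return None
        vals = [
            percent_id_per_gram(fr, m, meta, density_g_per_mL, True)
            for fr in sel
        ]
        return float(np.dot(weights, vals))

    whole = _weighted(mask, seg.source if seg is not None else None)
    if whole is None:
        raise ValueError("empty mask")
    aer = den = None
    if seg is not None:
        aer = _weighted(seg.aerated, seg.source)
        den = _weighted(seg.dense, seg.source)
    return UptakeResult(
        whole_lung_pct_id_g=whole,
        aerated_pct_id_g=aer,
        dense_pct_id_g=den,
        window_min=tuple(window),  # type: ignore[arg-type]
        decay_corrected=True,
        tissue_density_g_mL=density_g_per_mL,
    )


def tac_divergence(
    tac_a: TimeActivityCurve,
    tac_b: TimeActivityCurve,
    tolerance: float = 0.5,
) -> float | None:
    """Earliest mid-time from which ``tac_b`` persistently exceeds ``tac_a``.

    Returns the earliest mid-time t* such that ``b - a > tolerance`` at every
    point from t* onward, or ``None`` if no such time exists. The default
    tolerance is 0.5 %ID/g. Curves must share one mid-time grid.
    """
    ta = np.asarray(tac_a.mid_times_min)
    tb = np.asarray(tac_b.mid_times_min)
    if ta.shape != tb.shape or not np.allclose(ta, tb):
        raise ValueError("mismatched mid-time grids")
    diff = np.asarray(tac_b.uptake_pct_id_g) - np.asarray(tac_a.uptake_pct_id_g)
    above = diff > tolerance
    # earliest index from which all later points are above
    t_star = None
    for i in range(len(above) - 1, -1, -1):
        if not above[i]:
            break
        t_star = float(ta[i])
    return t_star


def median_tac(tacs: list[TimeActivityCurve], roi_label: str = "lung") -> TimeActivityCurve:
    """Pointwise median curve of TACs sharing one mid-time grid."""
    if not tacs:
        raise ValueError("no curves")
    t0 = np.asarray(tacs[0].mid_times_min)
    for t in tacs[1:]:
        if not np.allclose(np.asarray(t.mid_times_min), t0):
            raise ValueError("mismatched mid-time grids")
    med = np.median(np.array([t.uptake_pct_id_g for t in tacs]), axis=0)
    return TimeActivityCurve(
        mid_times_min=tuple(float(x) for x in t0),
        uptake_pct_id_g=tuple(float(x) for x in med),
        decay_corrected=all(t.decay_corrected for t in tacs),
        roi_label=roi_label,
    )
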