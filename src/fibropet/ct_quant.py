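"""CT-side quantification: lung density segmentation and mean lung density.

Fibrotic consolidation replaces air with tissue, so its CT attenuation rises
from strongly negative (aerated lung) towards soft-tissue values. The lung
ROI is partitioned by Hounsfield-unit thresholds into an *aerated*
compartment, ``[-800, -100)`` HU, and a *dense* (non-aerated) compartment,
``[-100, 300]`` HU. The two published bands share the -100 HU boundary
without saying which band owns it; the half-open-below convention keeps the
bands disjoint and total, and is configurable.

Voxels outside both bands (air below -800 HU, bone/metal above 300 HU) stay
in the lung ROI tally for mean lung density (MLD) but are excluded from
compartment uptake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_core import ROIMask, VolumeGrid, mask_statistics

__all__ = [
    "DensityThresholds",
    "DensitySegmentation",
    "CTResult",
    "segment_density",
    "mean_lung_density",
    "ct_result",
]


@dataclass(frozen=True)
class DensityThresholds:
    """HU cut points: aerated ``[aerated_low, aerated_high)``,
    dense ``[aerated_high, dense_high]``."""

    aerated_low: float = -800.0
    aerated_high: float = -100.0
    dense_high: float = 300.0

    def __post_init__(self) -> None:
        if not (self.aerated_low < self.aerated_high < self.dense_high):
            raise ValueError(
                "thresholds must satisfy aerated_low < aerated_high < dense_high"
            )


@dataclass
class DensitySegmentation:
    """Partition of a lung ROI into aerated / dense / excluded voxel sets."""

    aerated: ROIMask
    dense: ROIMask
    excluded: ROIMask
    thresholds: DensityThresholds
    source: VolumeGrid
    lung: ROIMask


@dataclass(frozen=True)
class CTResult:
    mean_lung_density: float
    lung_volume_mL: float
    aerated_volume_mL: float
    dense_volume_mL: float
    fibrosis_fraction: float


def _check_ct_inputs(ct: VolumeGrid, lung: ROIMask) -> None:
    if ct.modality != "CT":
        raise ValueError(f"modality mismatch: expected CT, got {ct.modality}")
    if lung.membership.shape != ct.values.shape:
        raise ValueError("lung mask not congruent with CT grid")
    if lung.voxel_count == 0:
        raise ValueError("empty lung mask")


def segment_density(
    ct: VolumeGrid,
    lung: ROIMask,
    thresholds: DensityThresholds | None = None,
) -> DensitySegmentation:
    """Threshold the lung ROI into aerated, dense and excluded compartments.

    The three output masks are pairwise disjoint and their union equals the
    input lung mask (partition invariant). Pure density thresholding — no
    morphological smoothing is applied.
    """
    thr = thresholds or DensityThresholds()
    _check_ct_inputs(ct, lung)
    hu = ct.values
    inside = lung.membership
    aerated = inside & (hu >= thr.aerated_low) & (hu < thr.aerated_high)
    dense = inside & (hu >= thr.aerated_high) & (hu <= thr.dense_high)
    excluded = inside & ~aerated & ~dense
    return DensitySegmentation(
        aerated=ROIMask(aerated, label="aerated"),
        dense=ROIMask(dense, label="dense"),
        excluded=ROIMask(excluded, label="excluded"),
        thresholds=thr,
        source=ct,
        lung=lung,
    )


def mean_lung_density(ct: VolumeGrid, lung: ROIMask) -> float:
    """Arithmetic mean HU over the full lung ROI (including out-of-band voxels)."""
    _check_ct_inputs(ct, lung)
    return mask_statistics(ct, lung)["mean"]


def ct_result(seg: DensitySegmentation, ct: VolumeGrid, lung: ROIMask) -> CTResult:
    """Summarise a segmentation: MLD, compartment volumes, fibrosis fraction.

    ``fibrosis_fraction = dense / (aerated + dense)`` — the fraction of
    in-band lung tissue occupied by consolidation.
    """
    if seg.source is not ct:
        raise ValueError("stale segmentation: produced from a different CT grid")
    _check_ct_inputs(ct, lung)
    vox_mL = ct.voxel_volume_mL
    n_a = seg.aerated.voxel_count
    n_d = seg.dense.voxel_count
    n_inband = n_a + n_d
    frac = n_d / n_inband if n_inband else 0.0
    return CTResult(
        mean_lung_density=mean_lung_density(ct, lung),
        lung_volume_mL=lung.voxel_count * vox_mL,
        aerated_volume_mL=n_a * vox_mL,
        dense_volume_mL=n_d * vox_mL,
        fibrosis_fraction=frac,
    )


def fibrosis_fraction(
    ct: VolumeGrid, lung: ROIMask, thresholds: DensityThresholds | None = None
) -> float:
    """Convenience: dense-band fraction of in-band lung tissue."""
    seg = segment_density(ct, lung, thresholds)
    return ct_result(seg, ct, lung).fibrosis_fraction


def hu_tissue_density(ct: VolumeGrid, mask: ROIMask) -> float:
    """Mean HU-derived mass density over a ROI: rho = 1 + HU/1000 g/mL,
    clamped at 0.05 g/mL. Optional alternative to the unit-density default
    used for %ID/g."""
    _check_ct_inputs(ct, mask)
    rho = np.clip(1.0 + ct.values[mask.membership] / 1000.0, 0.05, None)
    return float(rho.mean())
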