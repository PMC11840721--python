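"""Shared image data model, mask algebra and NIfTI I/O.

Conventions used throughout the package:

* world coordinates are RAS millimetres, voxel indices are 0-based, and the
  affine is axis-aligned (``world = origin + index * spacing``, voxel centres);
* PET volumes hold activity concentration in kBq/mL *as measured* (no decay
  pre-correction in files) — decay correction is an explicit pipeline step in
  :mod:`fibropet.pet_quant`;
* CT volumes hold Hounsfield units;
* PET frame timing is minutes post-injection, half-open ``[start, start+dur)``;
* modality and frame timing travel in a sidecar JSON next to each NIfTI file
  so the volumes stay readable by standard viewers.

Masks and images must share one grid (the scanner's PET/CT are hardware
co-registered); a congruence check with a clear error replaces registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GA68_HALF_LIFE_MIN",
    "VolumeGrid",
    "ROIMask",
    "AcquisitionMeta",
    "read_volume",
    "write_volume",
    "mask_statistics",
    "resample_mask",
]

#: Physical half-life of gallium-68 in minutes.
GA68_HALF_LIFE_MIN = 67.71

_HU_MIN, _HU_MAX = -1024.0, 3071.0


@dataclass
class VolumeGrid:
    """A 3D scalar image with geometry and acquisition-time metadata.

    Parameters
    ----------
    values
        3D array; HU for CT, activity concentration (kBq/mL) for PET.
    spacing
        Per-axis voxel edge length in mm (all > 0).
    origin
        World position (mm) of the centre of voxel (0, 0, 0).
    modality
        ``"CT"`` or ``"PET"``.
    frame_start_min, frame_duration_min
        PET frame timing in minutes post-injection; ``None`` for CT.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"
    frame_start_min: float | None = None
    frame_duration_min: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"non-3D image: got {self.values.ndim} dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing entries must be > 0, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.modality not in ("CT", "PET"):
            raise ValueError(f"modality must be 'CT' or 'PET', got {self.modality!r}")
        if self.modality == "PET":
            if self.values.min() < 0:
                raise ValueError("PET values must be >= 0")
            if self.frame_duration_min is not None and self.frame_duration_min <= 0:
                raise ValueError("frame_duration_min must be > 0")
        else:
            if self.values.min() < _HU_MIN or self.values.max() > _HU_MAX:
                raise ValueError(
                    f"CT values must lie in [{_HU_MIN:g}, {_HU_MAX:g}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    @property
    def voxel_volume_mL(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def frame_mid_min(self) -> float:
        """Mid-time of the PET frame in minutes post-injection."""
        if self.frame_start_min is None or self.frame_duration_min is None:
            raise ValueError("volume has no frame timing metadata")
        return self.frame_start_min + self.frame_duration_min / 2.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ROIMask:
    """Boolean voxel membership congruent with a :class:`VolumeGrid`."""

    membership: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.membership))


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injection metadata anchoring decay correction and %ID/g.

    ``injection_time_min`` is the reference clock zero: all frame times are
    minutes elapsed from it (minutes p.i.).
    """

    injected_activity_MBq: float
    injection_time_min: float = 0.0
    half_life_min: float = GA68_HALF_LIFE_MIN
    tracer_amount_nmol: float | None = None

    def __post_init__(self) -> None:
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected_activity_MBq must be > 0")
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be > 0")


def _require_congruent(grid: VolumeGrid, mask: ROIMask) -> None:
    if mask.membership.shape != grid.values.shape:
        raise ValueError(
            f"shape mismatch: mask {mask.membership.shape} vs grid {grid.values.shape}"
        )


def mask_statistics(grid: VolumeGrid, mask: ROIMask) -> dict[str, float]:
    """Mean value, voxel count and volume (mL) of a ROI.

    Raises on an empty mask so that "no voxels" is never silently reported
    as a zero mean.
    """
    _require_congruent(grid, mask)
    n = mask.voxel_count
    if n == 0:
        raise ValueError("empty mask")
    return {
        "mean": float(grid.values[mask.membership].mean()),
        "voxel_count": float(n),
        "volume_mL": n * grid.voxel_volume_mL,
    }


def resample_mask(mask: ROIMask, source: VolumeGrid, target: VolumeGrid) -> ROIMask:
    """Nearest-neighbour resampling of a mask between two axis-aligned grids.

    Each target voxel centre is mapped to the nearest source voxel; centres
    falling outside the source grid are set False. Used to carry CT-derived
    lung/compartment masks onto the PET grid.
    """
    _require_congruent(source, mask)
    out = np.zeros(target.shape, dtype=bool)
    idx = []
    inside = np.ones(target.shape, dtype=bool)
    for ax in range(3):
        n_t = target.shape[ax]
        coords = target.origin[ax] + np.arange(n_t) * target.spacing[ax]
        src = np.floor((coords - source.origin[ax]) / source.spacing[ax] + 0.5)
        src = src.astype(np.int64)
        ok = (src >= 0) & (src < source.shape[ax])
        shape = [1, 1, 1]
        shape[ax] = n_t
        inside &= ok.reshape(shape)
        idx.append(np.clip(src, 0, source.shape[ax] - 1))
    ii = idx[0][:, None, None]
    jj = idx[1][None, :, None]
    kk = idx[2][None, None, :]
    out = mask.membership[ii, jj, kk] & inside
    return ROIMask(out, label=mask.label)


# ---------------------------------------------------------------------------
# NIfTI I/O with sidecar metadata
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(grid: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float32) plus a sidecar JSON.

    Lossless for 32-bit float data; the sidecar carries modality, units and
    (for PET) frame timing.
    """
    path = Path(path)
    img = nib.Nifti1Image(grid.values.astype(np.float32), grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    sidecar = {
        "modality": grid.modality,
        "units": "HU" if grid.modality == "CT" else "kBq/mL",
        "frame_start_min": grid.frame_start_min,
        "frame_duration_min": grid.frame_duration_min,
        # full-precision geometry (the NIfTI affine is float32)
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI-1 volume and its sidecar JSON back into a VolumeGrid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"non-3D image: got {data.ndim} dimensions")
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ValueError(f"missing modality metadata: no sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    if "modality" not in meta:
        raise ValueError("missing modality metadata in sidecar")
    if "spacing_mm" in meta:
        spacing = tuple(float(s) for s in meta["spacing_mm"])
    if "origin_mm" in meta:
        origin = tuple(float(o) for o in meta["origin_mm"])
    return VolumeGrid(
        values=data,
        spacing=spacing,
        origin=origin,
        modality=meta["modality"],
        frame_start_min=meta.get("frame_start_min"),
        frame_duration_min=meta.get("frame_duration_min"),
    )


def write_mask(mask: ROIMask, grid: VolumeGrid, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI on the geometry of ``grid``."""
    _require_congruent(grid, mask)
    img = nib.Nifti1Image(mask.membership.astype(np.uint8), grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(Path(path)))


def read_mask(path: str | Path, label: str = "roi") -> ROIMask:
    """Read a uint8 NIfTI mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D image: got {data.ndim} dimensions")
    return ROIMask(data > 0, label=label)
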