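"""Ex vivo biodistribution emulation and analysis.

Gamma-counting of harvested organs is emulated as per-organ %ID/g values
with renal-dominant clearance (the tracer is a small hydrophilic peptide):
kidneys are always the hottest organ. Lung %ID/g follows the subject's
ground-truth window-averaged kinetic curve, so imaging and ex vivo counting
agree up to measurement noise. Fibrotic burden raises blood and heart
values (circulating collagen fragments) and lowers the urinary elimination.

"Elimination" is operationalised as the urinary excreted percent of the
injected dose at sacrifice — the emulated study never defines its
elimination quantity, so this definition is a declared stand-in.

Organ values are %ID/g against nominal mouse reference organ masses, so
%ID and %ID/g interconvert deterministically and a mass-balance check
(organs + excreted <= 100 %ID) can be enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging_core import AcquisitionMeta
from .phantom import GroundTruth, KineticParams, frame_mean_coefficients

__all__ = [
    "ORGANS",
    "ORGAN_MASS_G",
    "BiodistParams",
    "BiodistributionTable",
    "synthesize_biodistribution",
    "tissue_ratios",
    "elimination_metric",
    "tables_to_frame",
    "frame_to_tables",
]

ORGANS = (
    "lungs",
    "blood",
    "bladder+urine",
    "liver",
    "spleen",
    "heart",
    "muscle",
    "kidneys",
)

#: Nominal mouse reference organ masses (g) for %ID <-> %ID/g conversion.
ORGAN_MASS_G = {
    "lungs": 0.15,
    "blood": 1.5,
    "bladder+urine": 0.15,
    "liver": 1.3,
    "spleen": 0.10,
    "heart": 0.15,
    "muscle": 10.0,
    "kidneys": 0.40,
}


@dataclass(frozen=True)
class BiodistParams:
    """Baseline organ values and fibrosis effect sizes.

    ``*_per_burden`` multipliers scale linearly with the subject's fibrotic
    lung fraction, so control animals sit at baseline and effects grow with
    severity.
    """

    baseline_pct_id_g: tuple[tuple[str, float], ...] = (
        ("blood", 1.0),
        ("bladder+urine", 8.0),
        ("liver", 1.5),
        ("spleen", 1.2),
        ("heart", 0.8),
        ("muscle", 0.3),
        ("kidneys", 15.0),
    )
    blood_increase_per_burden: float = 1.5
    heart_increase_per_burden: float = 1.5
    baseline_excreted_pct_id: float = 60.0
    excretion_drop_per_burden: float = 0.5
    organ_noise_sd: float = 0.10
    excreted_noise_sd: float = 3.0
    window_min: tuple[float, float] = (15.0, 75.0)


@dataclass
class BiodistributionTable:
    """Per-organ %ID/g plus urinary excreted %ID for one subject-timepoint."""

    subject_id: str
    group: str
    timepoint: int
    organs: dict[str, float] = field(default_factory=dict)
    excreted_percent_id: float = 0.0

    def __post_init__(self) -> None:
        missing = [o for o in self.organs if o not in ORGANS]
        if missing:
            raise ValueError(f"unknown organs: {missing}")
        if any(v < 0 for v in self.organs.values()):
            raise ValueError("organ %ID/g must be >= 0")
        if not 0.0 <= self.excreted_percent_id <= 100.0:
            raise ValueError("excreted_percent_id must lie in [0, 100]")

    def total_percent_id(self) -> float:
        organs = sum(
            self.organs[o] * ORGAN_MASS_G[o] for o in self.organs
        )
        return organs + self.excreted_percent_id


def _analytic_window_uptake(
    truth: GroundTruth,
    kinetics: KineticParams,
    meta: AcquisitionMeta,
    window: tuple[float, float],
) -> float:
    """Window-averaged decay-free lung %ID/g from the ground-truth curve."""
    frame = (window[0], window[1] - window[0])
    a, s, _ = frame_mean_coefficients(kinetics, meta, frame, decayed=False)
    conc = a + s * truth.mean_lung_burden  # kBq/mL
    return 100.0 * conc / (meta.injected_activity_MBq * 1000.0)


def synthesize_biodistribution(
    subject_id: str,
    group: str,
    timepoint: int,
    truth: GroundTruth,
    kinetics: KineticParams,
    meta: AcquisitionMeta,
    seed,
    params: BiodistParams | None = None,
) -> BiodistributionTable:
    """Draw one organ table for a subject-timepoint.

    Deterministic for identical inputs and seed. Kidneys are drawn highest
    (enforced: the renal route dominates by construction). Lognormal
    measurement noise (sd ``organ_noise_sd`` on the log scale) perturbs each
    organ; excreted %ID gets additive noise clipped to [0, 100].
    """
    p = params or BiodistParams()
    rng = np.random.default_rng(seed)
    b = truth.true_fibrosis_fraction

    values = dict(p.baseline_pct_id_g)
    values["blood"] *= 1.0 + p.blood_increase_per_burden * b
    values["heart"] *= 1.0 + p.heart_increase_per_burden * b
    values["lungs"] = _analytic_window_uptake(truth, kinetics, meta, p.window_min)

    noisy = {
        o: float(v * rng.lognormal(0.0, p.organ_noise_sd))
        for o, v in values.items()
    }
    others = max(v for o, v in noisy.items() if o != "kidneys")
    noisy["kidneys"] = max(noisy["kidneys"], 1.05 * others)

    excreted = p.baseline_excreted_pct_id * (1.0 - p.excretion_drop_per_burden * b)
    excreted = float(np.clip(excreted + rng.normal(0.0, p.excreted_noise_sd), 0.0, 100.0))

    table = BiodistributionTable(
        subject_id=subject_id,
        group=group,
        timepoint=timepoint,
        organs=noisy,
        excreted_percent_id=excreted,
    )
    total = table.total_percent_id()
    if total > 100.0:  # mass balance: rescale organ retention
        scale = (100.0 - excreted) / (total - excreted)
        table.organs = {o: v * scale for o, v in table.organs.items()}
    return table


def tissue_ratios(table: BiodistributionTable) -> dict[str, float]:
    """Lung-to-blood and lung-to-muscle %ID/g ratios."""
    for denom in ("blood", "muscle"):
        if table.organs.get(denom, 0.0) <= 0:
            raise ValueError(f"zero denominator: {denom}")
    return {
        "lung_to_blood": table.organs["lungs"] / table.organs["blood"],
        "lung_to_muscle": table.organs["lungs"] / table.organs["muscle"],
    }


def elimination_metric(table: BiodistributionTable) -> float:
    """Urinary excreted %ID at sacrifice (the elimination measure)."""
    if table.excreted_percent_id is None:
        raise ValueError("missing excreted_percent_id")
    return float(table.excreted_percent_id)


def tables_to_frame(tables: list[BiodistributionTable]) -> pd.DataFrame:
    """Long-format organ table: subject_id, group, timepoint, organ,
    pct_id_per_g (excreted %ID carried as organ 'urine_excreted_pct_id')."""
    rows = []
    for t in tables:
        for organ, v in t.organs.items():
            rows.append(
                dict(
                    subject_id=t.subject_id,
                    group=t.group,
                    timepoint=t.timepoint,
                    organ=organ,
                    pct_id_per_g=v,
                )
            )
        rows.append(
            dict(
                subject_id=t.subject_id,
                group=t.group,
                timepoint=t.timepoint,
                organ="urine_excreted_pct_id",
                pct_id_per_g=t.excreted_percent_id,
            )
        )
    return pd.DataFrame(rows)


def frame_to_tables(df: pd.DataFrame) -> dict[tuple[str, int], BiodistributionTable]:
    """Inverse of :func:`tables_to_frame`, keyed by (subject_id, timepoint)."""
    out: dict[tuple[str, int], BiodistributionTable] = {}
    for (sid, group, day), sub in df.groupby(["subject_id", "group", "timepoint"]):
        organs = {}
        excreted = 0.0
        for _, row in sub.iterrows():
            if row["organ"] == "urine_excreted_pct_id":
                excreted = float(row["pct_id_per_g"])
            else:
                organs[row["organ"]] = float(row["pct_id_per_g"])
        out[(sid, int(day))] = BiodistributionTable(
            subject_id=sid,
            group=group,
            timepoint=int(day),
            organs=organs,
            excreted_percent_id=excreted,
        )
    return out
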