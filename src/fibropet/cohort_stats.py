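"""Cohort-level statistics: median/IQR summaries, rank tests, deltas and
predictive correlations.

The analysis layer is fully nonparametric, mirroring standard small-sample
preclinical practice: two-group contrasts use the Mann-Whitney U test
(exact p by full enumeration when the combined sample is small and tie-free,
otherwise a tie-corrected normal approximation), multi-group contrasts use
the Kruskal-Wallis H test with Dunn's rank post-hoc and Bonferroni
multiplication, and correlations default to Spearman's rho (exact
permutation p at small n). Summaries are median +/- interquartile range with
linear-interpolation (type-7) quartiles.

Exact enumeration limits: combined n <= 14 for Mann-Whitney, total n <= 8
for Kruskal-Wallis and Spearman — chosen for desk-scale runtime; above
them the documented approximations apply.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ct_quant import DensityThresholds, ct_result, segment_density
from .pet_quant import window_uptake
from .biodist import elimination_metric, tissue_ratios

__all__ = [
    "GroupComparison",
    "DunnResult",
    "CorrelationResult",
    "LongitudinalDelta",
    "StudyReport",
    "median_iqr",
    "mann_whitney",
    "kruskal_wallis",
    "dunn_bonferroni",
    "spearman",
    "delta_longitudinal",
    "cohort_deltas",
    "predictive_correlation",
    "quantify_cohort",
    "run_study_analysis",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Star annotation: *p<0.05, **p<0.01, ***p<0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    group_sizes: tuple[int, ...]
    method_detail: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass(frozen=True)
class DunnResult:
    """Dunn's pairwise rank post-hoc with Bonferroni adjustment."""

    labels: tuple[str, ...]
    z: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    n_comparisons: int

    def _idx(self, a: str, b: str) -> tuple[int, int]:
        return self.labels.index(a), self.labels.index(b)

    def adjusted_p(self, a: str, b: str) -> float:
        i, j = self._idx(a, b)
        return float(self.p_adjusted[i, j])

    def raw_p(self, a: str, b: str) -> float:
        i, j = self._idx(a, b)
        return float(self.p_raw[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_adjusted, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    rho: float
    p_value: float
    n: int
    x_label: str = "x"
    y_label: str = "y"
    group: str | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.rho) or -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValueError("rho must lie in [-1, 1]")


@dataclass(frozen=True)
class LongitudinalDelta:
    subject_id: str
    metric: str
    t0: int
    t1: int
    delta: float

    def __post_init__(self) -> None:
        if self.t1 <= self.t0:
            raise ValueError("t1 must be > t0")


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

def median_iqr(values: Sequence[float]) -> dict[str, float]:
    """Median and quartiles by the linear-interpolation (type-7) rule."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0], method="linear")
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _tie_sum(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    The U statistic uses mid-ranks for ties. With ``mode="exact"`` (or
    ``"auto"`` when the combined n <= 14 and there are no ties) the p-value
    is computed by full enumeration of all C(n_a+n_b, n_a) labelings,
    counting labelings whose U deviates from the null mean at least as much
    as observed. Otherwise a tie-corrected normal approximation (no
    continuity correction) is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0
    has_ties = np.unique(pooled).size < n

    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n <= 14 and not has_ties)
    if use_exact and has_ties:
        raise ValueError("exact enumeration requires tie-free data")

    if use_exact:
        rank_vals = np.arange(1, n + 1, dtype=float)
        offset = na * (na + 1) / 2.0
        dev = abs(u_a - mu) - 1e-9
        count = 0
        total = 0
        for comb in itertools.combinations(range(n), na):
            u = rank_vals[list(comb)].sum() - offset
            if abs(u - mu) >= dev:
                count += 1
            total += 1
        p = count / total
        detail = "exact enumeration"
    else:
        sigma2 = na * nb / 12.0 * ((n + 1) - _tie_sum(pooled) / (n * (n - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (u_a - mu) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
        detail = "tie-corrected normal approximation"
    return GroupComparison(
        test="mann_whitney",
        statistic=u_a,
        p_value=p,
        group_labels=("a", "b"),
        group_sizes=(na, nb),
        method_detail=detail,
    )


def _kw_h(groups_ranks: list[np.ndarray], pooled: np.ndarray) -> float:
    n = pooled.size
    h = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / r.size for r in groups_ranks
    ) - 3.0 * (n + 1)
    c = 1.0 - _tie_sum(pooled) / (n**3 - n)
    if c <= 0:
        return 0.0
    return h / c


def _group_assignments(positions: list[int], sizes: list[int]):
    if len(sizes) == 1:
        yield [tuple(positions)]
        return
    first, rest_sizes = sizes[0], sizes[1:]
    for comb in itertools.combinations(positions, first):
        taken = set(comb)
        rest = [p for p in positions if p not in taken]
        for tail in _group_assignments(rest, rest_sizes):
            yield [comb] + tail


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    exact: bool = False,
) -> GroupComparison:
    """Kruskal-Wallis H test with tie correction.

    p comes from the chi-square distribution with k-1 df; with
    ``exact=True`` and total n <= 8, p is computed by full enumeration of
    all assignments of the pooled observations to the group sizes.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("empty group")
    labels = tuple(labels) if labels else tuple(f"g{i}" for i in range(len(arrays)))
    sizes = [g.size for g in arrays]
    n = sum(sizes)
    if n < 3:
        raise ValueError("total n must be >= 3")
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    splits = np.cumsum(sizes)[:-1]
    h = _kw_h(list(np.split(ranks, splits)), pooled)

    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to total n <= 8")
        count = total = 0
        positions = list(range(n))
        for assign in _group_assignments(positions, sizes):
            gr = [ranks[list(pos)] for pos in assign]
            if _kw_h(gr, pooled) >= h - 1e-9:
                count += 1
            total += 1
        p = count / total
        detail = "exact enumeration"
    else:
        p = float(sps.chi2.sf(h, df=len(arrays) - 1))
        detail = "chi-square approximation"
    return GroupComparison(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=p,
        group_labels=labels,
        group_sizes=tuple(sizes),
        method_detail=detail,
    )


def dunn_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> DunnResult:
    """Dunn's z post-hoc on pooled mid-ranks, Bonferroni-adjusted.

    Pairwise p-values are multiplied by the number of comparisons
    k(k-1)/2 and clipped at 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size == 0 for g in arrays):
        raise ValueError("at least 2 non-empty groups required")
    labels = tuple(labels) if labels else tuple(f"g{i}" for i in range(len(arrays)))
    sizes = np.array([g.size for g in arrays])
    n = int(sizes.sum())
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    mean_ranks = [r.mean() for r in np.split(ranks, np.cumsum(sizes)[:-1])]
    tie_term = _tie_sum(pooled) / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    k = len(arrays)
    z = np.zeros((k, k))
    p_raw = np.ones((k, k))
    m = k * (k - 1) // 2
    for i, j in itertools.combinations(range(k), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        zij = 0.0 if var <= 0 else (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        z[i, j] = z[j, i] = zij
        pij = 2.0 * float(sps.norm.sf(abs(zij)))
        p_raw[i, j] = p_raw[j, i] = min(1.0, pij)
    p_adj = np.minimum(1.0, p_raw * m)
    np.fill_diagonal(p_adj, 1.0)
    return DunnResult(
        labels=labels, z=z, p_raw=p_raw, p_adjusted=p_adj, n_comparisons=m
    )


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 8,
    x_label: str = "x",
    y_label: str = "y",
    group: str | None = None,
) -> CorrelationResult:
    """Spearman rank correlation, two-sided.

    rho is the Pearson correlation of mid-ranks. For n <= ``exact_max_n``
    the p-value is exact by full permutation of one margin; above that a
    t-distribution approximation (df = n-2) applies. Constant input yields
    an undefined (NaN) correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("n must be >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return CorrelationResult(
            method="spearman", rho=float("nan"), p_value=float("nan"),
            n=n, x_label=x_label, y_label=y_label, group=group,
        )
    cx = (rx - rx.mean()) / (sx * math.sqrt(n))
    cy = (ry - ry.mean()) / (sy * math.sqrt(n))
    rho = float(np.dot(cx, cy))

    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (cy[perms] @ cx)
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-9))
        detail = "spearman"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = min(1.0, 2.0 * float(sps.t.sf(abs(t), df=n - 2)))
        detail = "spearman"
    return CorrelationResult(
        method=detail, rho=rho, p_value=p, n=n,
        x_label=x_label, y_label=y_label, group=group,
    )


# ---------------------------------------------------------------------------
# Longitudinal deltas and predictive correlations
# ---------------------------------------------------------------------------

def delta_longitudinal(
    values_by_day: Mapping[int, float],
    metric: str,
    subject_id: str = "",
    t0: int = 8,
    t1: int = 22,
) -> LongitudinalDelta:
    """Within-subject change metric(t1) - metric(t0)."""
    for t in (t0, t1):
        if t not in values_by_day:
            raise ValueError(f"missing timepoint D{t}")
    return LongitudinalDelta(
        subject_id=subject_id,
        metric=metric,
        t0=t0,
        t1=t1,
        delta=float(values_by_day[t1]) - float(values_by_day[t0]),
    )


def cohort_deltas(
    df: pd.DataFrame, metric: str, t0: int = 8, t1: int = 22
) -> pd.DataFrame:
    """Per-subject D{t0}->D{t1} deltas of one quantified metric."""
    wide = df.pivot_table(index=["subject_id", "group"], columns="day", values=metric)
    for t in (t0, t1):
        if t not in wide.columns:
            raise ValueError(f"missing timepoint D{t}")
    out = (wide[t1] - wide[t0]).dropna().rename("delta").reset_index()
    out["metric"] = metric
    out["t0"], out["t1"] = t0, t1
    return out


def predictive_correlation(
    df: pd.DataFrame,
    baseline_metric: str = "uptake",
    baseline_day: int = 8,
    outcome_metric: str = "mld",
    t0: int = 8,
    t1: int = 22,
    groups: Iterable[str] | None = None,
    min_n: int = 3,
) -> list[CorrelationResult]:
    """Per-group correlation of early uptake with later progression.

    x = ``baseline_metric`` at D{baseline_day}; y = within-subject change of
    ``outcome_metric`` between D{t0} and D{t1}. Groups with fewer than
    ``min_n`` complete subjects are skipped with a warning.
    """
    deltas = cohort_deltas(df, outcome_metric, t0, t1)
    base = df[df["day"] == baseline_day][["subject_id", "group", baseline_metric]]
    merged = deltas.merge(base, on=["subject_id", "group"])
    results = []
    for g in groups or sorted(merged["group"].unique()):
        sub = merged[merged["group"] == g]
        if len(sub) < min_n:
            warnings.warn(f"group {g!r} skipped: n={len(sub)} < {min_n}")
            continue
        results.append(
            spearman(
                sub[baseline_metric].to_numpy(),
                sub["delta"].to_numpy(),
                x_label=f"{baseline_metric}@D{baseline_day}",
                y_label=f"delta_{outcome_metric}_D{t0}-D{t1}",
                group=g,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Cohort quantification and the study report
# ---------------------------------------------------------------------------

def quantify_cohort(
    records,
    window: tuple[float, float] = (15.0, 75.0),
    thresholds: DensityThresholds | None = None,
    density_g_per_mL: float = 1.0,
) -> pd.DataFrame:
    """Run CT and PET quantification over a simulated (or loaded) cohort.

    One row per subject-timepoint with MLD, fibrosis fraction, window
    %ID/g (whole lung + compartments), biodistribution ratios and the
    phantom ground truth for reference.
    """
    rows = []
    for rec in records:
        for day in rec.days:
            tp = rec.timepoints[day]
            seg = segment_density(tp.ct, tp.lung, thresholds)
            cres = ct_result(seg, tp.ct, tp.lung)
            up = window_uptake(
                tp.frames, tp.lung, tp.meta, seg=seg, window=window,
                density_g_per_mL=density_g_per_mL,
            )
            row = dict(
                subject_id=rec.subject_id,
                group=rec.group,
                day=day,
                mld=cres.mean_lung_density,
                fibrosis_fraction=cres.fibrosis_fraction,
                lung_volume_mL=cres.lung_volume_mL,
                uptake=up.whole_lung_pct_id_g,
                aerated_uptake=up.aerated_pct_id_g,
                dense_uptake=up.dense_pct_id_g,
                true_fraction=tp.ground_truth.true_fibrosis_fraction,
            )
            if tp.biodistribution is not None:
                ratios = tissue_ratios(tp.biodistribution)
                row.update(ratios)
                row["excreted_pct_id"] = elimination_metric(tp.biodistribution)
                row["exvivo_lung_pct_id_g"] = tp.biodistribution.organs["lungs"]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StudyReport:
    """Deterministic analysis bundle of a quantified cohort."""

    summary: pd.DataFrame
    tests: dict
    deltas: pd.DataFrame
    delta_tests: dict
    correlations: list[CorrelationResult]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.deltas.to_csv(out / "deltas.csv", index=False)
        pd.DataFrame([asdict(c) for c in self.correlations]).to_csv(
            out / "correlations.csv", index=False
        )
        (out / "tests.json").write_text(
            json.dumps(
                {"per_day": self.tests, "deltas": self.delta_tests},
                indent=1,
                default=_jsonable,
            )
        )


def _jsonable(obj):
    if isinstance(obj, (GroupComparison, CorrelationResult, LongitudinalDelta)):
        return asdict(obj)
    if isinstance(obj, DunnResult):
        return {
            "labels": obj.labels,
            "p_adjusted": obj.p_adjusted.tolist(),
            "p_raw": obj.p_raw.tolist(),
            "z": obj.z.tolist(),
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _per_day_tests(df: pd.DataFrame, metric: str) -> dict:
    out: dict = {}
    for day, sub in df.groupby("day"):
        sub = sub.dropna(subset=[metric])
        glabels = sorted(sub["group"].unique())
        if len(glabels) < 2:
            continue
        arrays = [sub[sub["group"] == g][metric].to_numpy() for g in glabels]
        entry: dict = {}
        entry["kruskal_wallis"] = kruskal_wallis(arrays, labels=glabels)
        entry["posthoc"] = dunn_bonferroni(arrays, labels=glabels)
        if "BLM" in glabels and "NaCl" in glabels:
            entry["mann_whitney_BLM_vs_NaCl"] = mann_whitney(
                sub[sub["group"] == "BLM"][metric].to_numpy(),
                sub[sub["group"] == "NaCl"][metric].to_numpy(),
            )
        out[int(day)] = entry
    return out


def run_study_analysis(
    df: pd.DataFrame,
    t0: int = 8,
    t1: int = 22,
    correlate_groups: tuple[str, ...] = (
        "BLM",
        "BLM+nintedanib",
        "BLM+tofacitinib",
    ),
) -> StudyReport:
    """Full study-level analysis of a quantified cohort DataFrame.

    Produces per-group median/IQR of uptake and MLD per timepoint,
    Kruskal-Wallis + Dunn-Bonferroni across groups per timepoint, the BLM
    vs control Mann-Whitney contrast, D{t0}->D{t1} delta metrics with group
    comparisons, the pooled MLD-uptake correlation and the per-group
    predictive correlations. Deterministic given its input.
    """
    if df.empty:
        raise ValueError("unquantified cohort: empty input")
    metrics = [m for m in ("uptake", "mld", "lung_to_blood", "lung_to_muscle",
                           "excreted_pct_id") if m in df.columns]
    summary_rows = []
    for (group, day), sub in df.groupby(["group", "day"]):
        for metric in metrics:
            vals = sub[metric].dropna()
            if vals.empty:
                continue
            mi = median_iqr(vals.to_numpy())
            summary_rows.append(
                dict(group=group, day=int(day), metric=metric, n=len(vals), **mi)
            )
    summary = pd.DataFrame(summary_rows).sort_values(
        ["metric", "day", "group"], ignore_index=True
    )

    tests = {m: _per_day_tests(df, m) for m in ("uptake", "mld") if m in df.columns}

    delta_frames = []
    delta_tests: dict = {}
    have_both = {t0, t1} <= set(df["day"].unique())
    if have_both:
        for metric in ("uptake", "mld"):
            if metric not in df.columns:
                continue
            d = cohort_deltas(df, metric, t0, t1)
            delta_frames.append(d)
            glabels = sorted(d["group"].unique())
            if len(glabels) >= 2:
                arrays = [d[d["group"] == g]["delta"].to_numpy() for g in glabels]
                entry = {
                    "kruskal_wallis": kruskal_wallis(arrays, labels=glabels),
                    "posthoc": dunn_bonferroni(arrays, labels=glabels),
                }
                for treated in ("BLM+nintedanib", "BLM+tofacitinib"):
                    if "BLM" in glabels and treated in glabels:
                        entry[f"mann_whitney_BLM_vs_{treated}"] = mann_whitney(
                            d[d["group"] == "BLM"]["delta"].to_numpy(),
                            d[d["group"] == treated]["delta"].to_numpy(),
                        )
                delta_tests[metric] = entry
    deltas = (
        pd.concat(delta_frames, ignore_index=True)
        if delta_frames
        else pd.DataFrame(columns=["subject_id", "group", "delta", "metric", "t0", "t1"])
    )

    correlations: list[CorrelationResult] = []
    pooled = df.dropna(subset=["mld", "uptake"])
    if len(pooled) >= 3:
        correlations.append(
            spearman(
                pooled["mld"].to_numpy(),
                pooled["uptake"].to_numpy(),
                x_label="mld",
                y_label="uptake",
                group="pooled",
            )
        )
    if have_both:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            correlations.extend(
                predictive_correlation(
                    df,
                    groups=[g for g in correlate_groups if g in set(df["group"])],
                    t0=t0,
                    t1=t1,
                )
            )
    return StudyReport(
        summary=summary,
        tests=tests,
        deltas=deltas,
        delta_tests=delta_tests,
        correlations=correlations,
    )
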