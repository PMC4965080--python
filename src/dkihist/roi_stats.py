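"""ROI-level summaries and the study's rank-based statistics.

The unit of analysis is the ROI (tumor or matched normal region), not the
patient; within-patient clustering is deliberately not modeled, replicating
the original univariate design.  Two tests are provided:

* Wilcoxon rank-sum (Mann-Whitney) with midranks for ties.  For combined
  sample sizes up to 20 the two-sided p-value is computed by exact
  enumeration of all C(n1+n2, n1) group assignments of the pooled midranks
  (a conditional permutation test, valid with or without ties); larger
  samples use the normal approximation with tie-corrected variance and a
  continuity correction.
* Spearman rank correlation: Pearson correlation of midranks, with a
  two-sided p-value from t = rho*sqrt((n-2)/(1-rho**2)) on n-2 degrees of
  freedom.

``run_study_analyses`` emits the full comparison grid: tumor vs normal and
Gleason-group (>=4+3 vs <=3+4) rank-sum tests on each tissue fraction and
each DKI median, plus Spearman correlations between every fraction and
every DKI median within the normal and tumor strata — 22 rows in all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, t as t_dist

from .histo_segmentation import TissueFractions

__all__ = [
    "ROIRecord",
    "CohortTable",
    "TestResult",
    "COHORT_COLUMNS",
    "roi_median",
    "rank_sum_test",
    "spearman_correlation",
    "run_study_analyses",
    "format_report",
]

EXACT_ENUMERATION_LIMIT = 20
SIGNIFICANCE_LEVEL = 0.05

COHORT_COLUMNS = (
    "patient_id",
    "roi_id",
    "tissue",
    "gs_group",
    "median_d_app",
    "median_k_app",
    "cellularity",
    "fsm",
    "luminal",
    "area_mm2",
)

_FRACTION_VARS = ("cellularity", "fsm", "luminal")
_DKI_VARS = ("median_d_app", "median_k_app")


@dataclass(frozen=True)
class ROIRecord:
    """One ROI row: identifiers, DKI medians (D in 10^-3 mm²/s) and tissue
    composition."""

    patient_id: str
    roi_id: str
    tissue: str  # "tumor" | "normal"
    gs_group: str  # "low" (<=3+4) | "high" (>=4+3) | "none"
    median_d_app: float
    median_k_app: float
    fractions: TissueFractions
    area_mm2: float

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be tumor|normal, got {self.tissue}")
        if self.gs_group not in ("low", "high", "none"):
            raise ValueError(f"gs_group must be low|high|none, got {self.gs_group}")
        if self.tissue == "normal" and self.gs_group != "none":
            raise ValueError("normal tissue must have gs_group='none'")
        if self.tissue == "tumor" and self.gs_group == "none":
            raise ValueError("tumor tissue needs a gs_group of low|high")
        if not (self.median_d_app > 0 and self.median_k_app > 0):
            raise ValueError("DKI medians must be positive")
        if not self.area_mm2 > 0:
            raise ValueError("area must be > 0")


@dataclass
class CohortTable:
    """Collection of ROI records convertible to/from the flat CSV schema."""

    records: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": r.patient_id,
                "roi_id": r.roi_id,
                "tissue": r.tissue,
                "gs_group": r.gs_group,
                "median_d_app": r.median_d_app,
                "median_k_app": r.median_k_app,
                "cellularity": r.fractions.cellularity,
                "fsm": r.fractions.fsm,
                "luminal": r.fractions.luminal,
                "area_mm2": r.area_mm2,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        _check_columns(df)
        records = [
            ROIRecord(
                patient_id=str(row.patient_id),
                roi_id=str(row.roi_id),
                tissue=str(row.tissue),
                gs_group=str(row.gs_group),
                median_d_app=float(row.median_d_app),
                median_k_app=float(row.median_k_app),
                fractions=TissueFractions(
                    cellularity=float(row.cellularity),
                    fsm=float(row.fsm),
                    luminal=float(row.luminal),
                ),
                area_mm2=float(row.area_mm2),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records=records)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test: statistic, two-sided p, sizes and method."""

    statistic: float
    p_value: float
    n1: int
    n2: int | None
    method: str  # "exact" | "normal_approx" | "t_approx"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def roi_median(parameter_map: np.ndarray, mask: np.ndarray) -> float:
    """Median of non-missing masked voxels (even counts average the two
    central order statistics; NaN-flagged voxels are excluded)."""
    parameter_map = np.asarray(parameter_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if parameter_map.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    values = parameter_map[mask]
    if values.size == 0:
        raise ValueError("mask selects no voxels")
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("all masked voxels are missing")
    return float(np.median(values))


def rank_sum_test(x, y) -> TestResult:
    """Wilcoxon rank-sum test; statistic is the midrank sum of ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    total = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (total + 1) / 2.0

    if total <= EXACT_ENUMERATION_LIMIT:
        dev_obs = abs(w_obs - mu) - 1e-12  # float-midrank tolerance
        hits = sum(
            1
            for combo in combinations(range(total), n1)
            if abs(sum(ranks[i] for i in combo) - mu) >= dev_obs
        )
        p = hits / math.comb(total, n1)
        method = "exact"
    else:
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
        if var <= 0:  # all values identical
            p = 1.0
        else:
            z = (w_obs - mu - 0.5 * np.sign(w_obs - mu)) / math.sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(abs(z))))
        method = "normal_approx"
    return TestResult(statistic=w_obs, p_value=p, n1=n1, n2=n2, method=method)


def spearman_correlation(x, y) -> TestResult:
    """Spearman rho (Pearson correlation of midranks) with a t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    rx, ry = rankdata(x), rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("correlation undefined for constant ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(t_dist.sf(abs(t), df=n - 2))
    return TestResult(statistic=rho, p_value=min(p, 1.0), n1=n, n2=None, method="t_approx")


def _check_columns(df: pd.DataFrame) -> None:
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise KeyError(f"cohort table is missing required column '{col}'")


def run_study_analyses(table) -> pd.DataFrame:
    """Full comparison grid over a cohort table (DataFrame or CohortTable).

    Rows: tumor-vs-normal rank-sum on the 3 fractions + 2 DKI medians (5),
    GS-high-vs-low rank-sum on the same (5), and Spearman correlations of
    each fraction with each DKI median within the normal and tumor strata
    (12) — 22 rows total.
    """
    if isinstance(table, CohortTable):
        df = table.to_dataframe()
    else:
        df = pd.DataFrame(table)
    _check_columns(df)

    tumor = df[df["tissue"] == "tumor"]
    normal = df[df["tissue"] == "normal"]
    gs_low = tumor[tumor["gs_group"] == "low"]
    gs_high = tumor[tumor["gs_group"] == "high"]
    variables = list(_FRACTION_VARS) + list(_DKI_VARS)

    rows = []
    for var in variables:
        res = rank_sum_test(tumor[var].to_numpy(), normal[var].to_numpy())
        rows.append(("tumor_vs_normal", var, "all", res))
    for var in variables:
        res = rank_sum_test(gs_high[var].to_numpy(), gs_low[var].to_numpy())
        rows.append(("gs_high_vs_low", var, "tumor", res))
    for stratum_name, stratum in (("normal", normal), ("tumor", tumor)):
        for dki_var in _DKI_VARS:
            for frac_var in _FRACTION_VARS:
                res = spearman_correlation(
                    stratum[dki_var].to_numpy(), stratum[frac_var].to_numpy()
                )
                rows.append(("spearman", f"{dki_var}~{frac_var}", stratum_name, res))

    return pd.DataFrame(
        [
            {
                "comparison": comp,
                "variable": var,
                "stratum": stratum,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n1": res.n1,
                "n2": res.n2 if res.n2 is not None else 0,
                "method": res.method,
            }
            for comp, var, stratum, res in rows
        ]
    )


def format_report(results: pd.DataFrame) -> str:
    """Human-readable report with p < 0.05 flags."""
    lines = [
        "ROI-level analysis (unit of analysis is the ROI; within-patient",
        "clustering is not modeled).  * marks p < 0.05 (two-sided).",
        "",
        f"{'comparison':<16} {'variable':<28} {'stratum':<8} "
        f"{'statistic':>10} {'p':>10}  method",
    ]
    for _, row in results.iterrows():
        flag = "*" if row.p_value < SIGNIFICANCE_LEVEL else " "
        lines.append(
            f"{row.comparison:<16} {row.variable:<28} {row.stratum:<8} "
            f"{row.statistic:>10.4f} {row.p_value:>10.4g}{flag} {row.method}"
        )
    return "\n".join(lines) + "\n"
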