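"""Plan-comparison reports: step bolus vs conformal bolus.

Assembles, per case, the DVH-derived dosimetric parameters for the two
bolus types — normalised chest-wall mean dose, mean dose to the
ipsilateral lung and heart, conformity index at the 90% isodose, and the
chest-wall dose standard deviation (homogeneity) — together with percent
changes and cohort mean/median rows.

The shipped ``reference_cohort.csv`` carries the per-patient printed
values of a published six-patient post-mastectomy cohort comparing the
two bolus types; it serves as a worked input for the percent-change and
cohort-aggregation arithmetic and as a regression fixture.

Display rounding is half-away-from-zero at the printed precision
(percent changes: integer when |value| >= 10, one decimal place
otherwise); raw unrounded values are always retained in the exported
records.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CHEST_WALL, HEART, LUNG_IPSI, StructureSet
from .dvh import (
    DoseGrid,
    conformity_index,
    differential_dvh,
    dose_mean_std,
    normalize_to_equal_cw_mean,
)

__all__ = [
    "percent_change",
    "round_half_away",
    "format_percent_change",
    "cohort_aggregate",
    "compare_plans",
    "load_reference_cohort",
    "PlanComparison",
]


def percent_change(conv: float, new: float) -> float:
    """100 x (new - conv) / conv; the sign convention used throughout
    (negative = the conformal bolus lowered the metric)."""
    if conv == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    return 100.0 * (new - conv) / conv


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed clinical tables,
    unlike numpy's banker's rounding). Operates on the shortest decimal
    representation so that e.g. 4.475 -> 4.48 despite binary storage."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def format_percent_change(pct: float) -> str:
    """Printed style: integer when |value| >= 10, one decimal otherwise."""
    if abs(pct) >= 10:
        return f"{round_half_away(pct):.0f}%"
    return f"{round_half_away(pct, 1):.1f}%"


def cohort_aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Column-wise mean and median rows over a cohort of case records.

    Median of an even count is the midpoint of the central pair. Only
    numeric columns are aggregated; returns a two-row frame indexed
    'mean'/'median'.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    num = records.select_dtypes(include=[np.number])
    return pd.DataFrame(
        {"mean": num.mean(), "median": num.median()}
    ).T


def load_reference_cohort() -> pd.DataFrame:
    """The shipped six-patient printed-value fixture."""
    with resources.files("bolusforge.data").joinpath("reference_cohort.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class PlanComparison:
    """Per-case dosimetric comparison of two plans plus cohort rows."""

    cases: pd.DataFrame
    aggregates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path: str | Path) -> None:
        self.cases.to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [
            "Plan comparison (conventional step vs conformal bolus)",
            "rounding: half away from zero; % change printed at table precision",
            self.cases.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        if len(self.aggregates):
            lines += ["-- cohort --", self.aggregates.to_string(
                float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)


def compare_plans(
    dose_conv: DoseGrid,
    dose_new: DoseGrid,
    structs: StructureSet,
    prescription_Gy: float,
    structs_new: StructureSet | None = None,
    case: str | int = 1,
    ci_level: float = 0.90,
    bin_width_Gy: float = 0.1,
    cw_reference_mean_Gy: float | None = None,
) -> PlanComparison:
    """Full dosimetric comparison of a step plan and a conformal plan.

    Both plans are first normalised to the same chest-wall mean dose
    (the conventional plan's, unless ``cw_reference_mean_Gy`` is given) so
    normal-organ doses are compared between equivalently normalised
    plans. ``structs_new`` allows each plan its own structure set (the
    two boluses differ); chest wall, lung and heart masks must agree.
    """
    s_conv, s_new = structs, (structs_new or structs)
    for role in (CHEST_WALL, LUNG_IPSI, HEART):
        if role not in s_conv or role not in s_new:
            raise KeyError(f"structure {role} missing from a plan")
    cw = s_conv[CHEST_WALL]
    ref = cw_reference_mean_Gy
    if ref is None:
        ref = float(np.asarray(dose_conv.dose.values)[cw].mean())
    d_conv = normalize_to_equal_cw_mean(dose_conv, cw, ref)
    d_new = normalize_to_equal_cw_mean(dose_new, cw, ref)

    def metrics(dg: DoseGrid, ss: StructureSet) -> dict[str, float]:
        out: dict[str, float] = {}
        for key, role in (("cw", CHEST_WALL), ("lung", LUNG_IPSI), ("heart", HEART)):
            stats = dose_mean_std(
                differential_dvh(dg, ss[role], bin_width_Gy, structure=role)
            )
            out[f"{key}_dmean"] = stats.D_mean_Gy
            out[f"{key}_dstd"] = stats.D_std_Gy
        out["ci"] = conformity_index(dg, ss[CHEST_WALL], prescription_Gy, ci_level).ci
        return out

    mc, mn = metrics(d_conv, s_conv), metrics(d_new, s_new)
    row = {
        "case": case,
        "cw_dmean_norm_Gy": mc["cw_dmean"],
        "lung_dmean_conv_Gy": mc["lung_dmean"],
        "lung_dmean_3d_Gy": mn["lung_dmean"],
        "lung_pct_change": percent_change(mc["lung_dmean"], mn["lung_dmean"]),
        "heart_dmean_conv_Gy": mc["heart_dmean"],
        "heart_dmean_3d_Gy": mn["heart_dmean"],
        "heart_pct_change": percent_change(mc["heart_dmean"], mn["heart_dmean"]),
        "ci_conv": mc["ci"],
        "ci_3d": mn["ci"],
        "ci_pct_change": percent_change(mc["ci"], mn["ci"]),
        "cw_dstd_conv_Gy": mc["cw_dstd"],
        "cw_dstd_3d_Gy": mn["cw_dstd"],
        "cw_dstd_pct_change": percent_change(mc["cw_dstd"], mn["cw_dstd"]),
    }
    cases = pd.DataFrame([row])
    return PlanComparison(cases, cohort_aggregate(cases))
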