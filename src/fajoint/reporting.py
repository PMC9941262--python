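"""Cohort summaries, per-age intake tables, and the CSV dialects.

Percentages are rounded half-up to match the one-decimal style of printed
cohort tables (and to zero decimals where whole-number percentages are
reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["round_half_up", "percentage", "mean_record_days",
           "CohortSummary", "cohort_summary", "median_iqr_by_age",
           "write_cohort", "read_cohort"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (0.05 -> 0.1)."""
    quant = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quant, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """100 * count / total, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


def mean_record_days(total_record_days: int, n_children: int) -> float:
    """Average food-record days per child, one decimal."""
    if n_children <= 0:
        raise ValueError("need at least one child")
    return round_half_up(total_record_days / n_children, 1)


def _count_pct(series: pd.Series, level) -> tuple[int, float]:
    n = int((series == level).sum())
    return n, percentage(n, len(series))


@dataclass
class CohortSummary:
    """Table-1-style description of one analysis cohort."""

    outcome: str
    n_total: int
    n_events: int
    incidence_pct: float
    median_event_age: float
    iqr_event_age: tuple[float, float]
    by_sex: dict = field(default_factory=dict)
    by_hla: dict = field(default_factory=dict)
    by_familial: dict = field(default_factory=dict)
    total_record_days: int = 0
    mean_record_days: float = 0.0
    dropout_pct: dict = field(default_factory=dict)


def cohort_summary(children: pd.DataFrame, records: pd.DataFrame | None = None,
                   outcome: str = "ia") -> CohortSummary:
    """Cohort counts, cumulative incidence, onset-age quartiles, covariate
    distribution, record-day totals and dropout percentages.

    Incidence is 100 x events / total rounded half-up to one decimal;
    mean record days is total record days / children, one decimal.
    """
    if len(children) == 0:
        raise ValueError("empty cohort")
    status = children[f"{outcome}_status"].to_numpy()
    ages = children.loc[status == 1, f"{outcome}_age"].to_numpy(float)
    n, ev = len(children), int(status.sum())
    med = float(np.median(ages)) if ev else float("nan")
    iqr = (tuple(np.percentile(ages, [25, 75])) if ev
           else (float("nan"), float("nan")))
    total_days = int(records["n_days"].sum()) if records is not None else 0
    dropout = {}
    censor = children["censor_age"].to_numpy(float)
    no_event = status == 0
    for a in (1.0, 2.0, 6.0):
        dropout[a] = percentage(int(((censor < a) & no_event).sum()), n, 0)
    return CohortSummary(
        outcome=outcome, n_total=n, n_events=ev,
        incidence_pct=percentage(ev, n),
        median_event_age=med, iqr_event_age=iqr,
        by_sex={lv: _count_pct(children["sex"], lv)
                for lv in ("male", "female")},
        by_hla={lv: _count_pct(children["hla_risk"], lv)
                for lv in ("high", "moderate")},
        by_familial={lv: _count_pct(children["familial_diabetes"], lv)
                     for lv in ("yes", "no", "missing")},
        total_record_days=total_days,
        mean_record_days=mean_record_days(total_days, n) if records is not None
        else 0.0,
        dropout_pct=dropout,
    )


def median_iqr_by_age(records: pd.DataFrame, column: str) -> pd.DataFrame:
    """Median (IQR) intake per schedule age with record-day counts.

    Quantiles use the linear-interpolation convention, the same one used for
    printed intake tables.
    """
    rows = []
    for age, grp in records.groupby("age"):
        v = grp[column].to_numpy(float)
        q25, q50, q75 = np.percentile(v, [25, 50, 75])
        rows.append({"age": float(age), "n_records": len(grp),
                     "n_record_days": int(grp["n_days"].sum()),
                     "median": q50, "q25": q25, "q75": q75})
    return pd.DataFrame(rows).sort_values("age").reset_index(drop=True)


# -- CSV dialects ----------------------------------------------------------

def write_cohort(children: pd.DataFrame, records: pd.DataFrame,
                 children_path, records_path) -> None:
    children.to_csv(children_path, index=False)
    records.to_csv(records_path, index=False)


def read_cohort(children_path, records_path):
    children = pd.read_csv(children_path,
                           dtype={"child_id": str},
                           keep_default_na=True)
    if "breastfed_at_3mo" in children.columns:
        children["breastfed_at_3mo"] = children["breastfed_at_3mo"].astype(bool)
    records = pd.read_csv(records_path, dtype={"child_id": str})
    return children, records
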