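"""Last-year-of-life expenditure decomposition.

Summaries of per-patient medical spending in the 12 months before death:
per-service-category tables (% users, mean, SD, % of total, median, IQR
width), short-window (last 3 months) spending shares, top-expenditure-
decile summaries, and per-pathway-cluster cost summaries and shares.

Conventions (fixed and documented):

* Means, medians and quartiles are over ALL cohort patients, zero-cost
  patients included; "% users" reports category uptake separately.
* The IQR is reported as a single width, Q3 - Q1, with linear-interpolation
  quartiles (numpy default).
* SD is the sample standard deviation (0 for a single patient).
* The top expenditure decile contains N - floor(0.9 N) patients; ties at
  the threshold are resolved by a stable rank on patient id.
* Values are kept at full precision; rounding to whole euros / one-decimal
  percentages belongs to the report-rendering layer only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class ServiceCategory(str, Enum):
    """The eleven service categories of the expenditure decomposition."""

    ACUTE_HOSPITAL = "acute_hospital"
    REHABILITATION = "rehabilitation"
    HOSPITAL_AT_HOME = "hospital_at_home"
    NURSING_SERVICES = "nursing_services"
    OUTPATIENT_VISITS = "outpatient_visits"
    PHYSIO_OTHER = "physio_other"
    EQUIPMENT_DEVICES = "equipment_devices"
    PHARMACY = "pharmacy"
    EXPENSIVE_HOSPITAL_DRUGS = "expensive_hospital_drugs"
    TRANSPORTATION = "transportation"
    PROCEDURES_IMAGING = "procedures_imaging"


CATEGORY_LABELS = {
    ServiceCategory.ACUTE_HOSPITAL: "Acute hospital care",
    ServiceCategory.REHABILITATION: "Rehabilitation care",
    ServiceCategory.HOSPITAL_AT_HOME: "Hospital at home",
    ServiceCategory.NURSING_SERVICES: "Nursing services",
    ServiceCategory.OUTPATIENT_VISITS: "Outpatient visits",
    ServiceCategory.PHYSIO_OTHER: "Physical therapy and other services",
    ServiceCategory.EQUIPMENT_DEVICES: "Medical equipment and devices",
    ServiceCategory.PHARMACY: "Pharmacy",
    ServiceCategory.EXPENSIVE_HOSPITAL_DRUGS: "Expensive hospital drugs",
    ServiceCategory.TRANSPORTATION: "Transportation",
    ServiceCategory.PROCEDURES_IMAGING: "Procedures/imaging",
}

CATEGORY_CODES = [c.value for c in ServiceCategory]

CLAIM_COLUMNS = ["patient_id", "days_before_death", "category", "cost"]


def validate_claims(claims: pd.DataFrame, cohort_ids=None) -> pd.DataFrame:
    missing = [c for c in CLAIM_COLUMNS if c not in claims.columns]
    if missing:
        raise ValueError(f"claims table missing columns {missing}")
    if len(claims):
        if claims["cost"].min() < 0:
            raise ValueError("claim costs must be non-negative")
        d = claims["days_before_death"]
        if d.min() < 0 or d.max() > 364:
            raise ValueError("days_before_death must lie in [0, 364]")
        bad = set(claims["category"].unique()) - set(CATEGORY_CODES)
        if bad:
            raise ValueError(f"unknown service categories {sorted(bad)}")
        if cohort_ids is not None:
            unknown = set(claims["patient_id"].unique()) - set(cohort_ids)
            if unknown:
                raise ValueError(
                    f"claims reference patients outside the cohort: "
                    f"{sorted(unknown)[:5]}"
                )
    return claims


@dataclass
class CostSummaryTable:
    """Per-service-category expenditure summary over a cohort.

    ``table`` has one row per category plus a "total" row, columns
    pct_users, mean, sd, pct_of_total, median, iqr.  ``n`` is the cohort
    size the statistics are computed over.
    """

    table: pd.DataFrame
    n: int
    window_days: int = 365

    def to_display(self) -> pd.DataFrame:
        """Rounded rendering: whole euros, one-decimal percentages."""
        out = self.table.copy()
        out.index = [
            CATEGORY_LABELS.get(ServiceCategory(c), "Total") if c != "total" else "Total"
            for c in out.index
        ]
        for col in ("mean", "sd", "median", "iqr"):
            out[col] = out[col].round(0).astype(int)
        for col in ("pct_users", "pct_of_total"):
            out[col] = out[col].round(1)
        return out


def patient_category_totals(
    claims: pd.DataFrame, cohort_ids, window_days: int = 365
) -> pd.DataFrame:
    """Per-patient, per-category spending totals over the window.

    Rows are all cohort patients (zeros included), columns the 11
    categories; only claims with ``days_before_death < window_days`` count.
    """
    validate_claims(claims, cohort_ids)
    sub = claims[claims["days_before_death"] < window_days]
    pivot = sub.pivot_table(
        index="patient_id", columns="category", values="cost",
        aggfunc="sum", fill_value=0.0,
    )
    return pivot.reindex(index=list(cohort_ids), columns=CATEGORY_CODES,
                         fill_value=0.0).fillna(0.0)


def patient_totals(claims: pd.DataFrame, cohort_ids, window_days: int = 365) -> pd.Series:
    """Per-patient total spending over the window (zeros included)."""
    return patient_category_totals(claims, cohort_ids, window_days).sum(axis=1)


def service_cost_table(
    claims: pd.DataFrame, cohort_ids, window_days: int = 365
) -> CostSummaryTable:
    """Expenditure summary by service category.

    Parameters
    ----------
    claims : DataFrame with columns patient_id, days_before_death, category, cost
    cohort_ids : all cohort patient ids (patients without claims count as zeros)
    window_days : claims with ``days_before_death < window_days`` are included
    """
    if not 1 <= window_days <= 365:
        raise ValueError("window_days must lie in 1..365")
    cohort_ids = list(cohort_ids)
    n = len(cohort_ids)
    if n == 0:
        raise ValueError("cohort is empty")
    per_pat = patient_category_totals(claims, cohort_ids, window_days)
    totals = per_pat.sum(axis=1)

    sub = claims[claims["days_before_death"] < window_days]
    users = sub.groupby("category", observed=False)["patient_id"].nunique()

    grand_total = float(totals.sum())
    rows = {}
    for cat in CATEGORY_CODES:
        col = per_pat[cat].to_numpy(dtype=float)
        rows[cat] = {
            "pct_users": 100.0 * float(users.get(cat, 0)) / n,
            "mean": float(col.sum()) / n,
            "sd": float(np.std(col, ddof=1)) if n > 1 else 0.0,
            "pct_of_total": 100.0 * float(col.sum()) / grand_total if grand_total else 0.0,
            "median": float(np.median(col)),
            "iqr": float(np.percentile(col, 75) - np.percentile(col, 25)),
        }
    tot = totals.to_numpy(dtype=float)
    any_user = sub["patient_id"].nunique()
    rows["total"] = {
        "pct_users": 100.0 * any_user / n,
        "mean": float(tot.sum()) / n,
        "sd": float(np.std(tot, ddof=1)) if n > 1 else 0.0,
        "pct_of_total": 100.0 if grand_total else 0.0,
        "median": float(np.median(tot)),
        "iqr": float(np.percentile(tot, 75) - np.percentile(tot, 25)),
    }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[CATEGORY_CODES + ["total"]]
    return CostSummaryTable(table, n, window_days)


def window_share(
    claims: pd.DataFrame, cohort_ids=None, short_window: int = 90,
    total_window: int = 365,
) -> float:
    """Share of total spending incurred in the last ``short_window`` days.

    Returns (spending with days_before_death < short_window) divided by
    spending within ``total_window``; 0 by convention when there is no
    spending at all.
    """
    if short_window > total_window:
        raise ValueError("short_window cannot exceed total_window")
    validate_claims(claims, cohort_ids)
    total = float(claims.loc[claims["days_before_death"] < total_window, "cost"].sum())
    if total == 0:
        return 0.0
    short = float(claims.loc[claims["days_before_death"] < short_window, "cost"].sum())
    return short / total


@dataclass(frozen=True)
class DecileSummary:
    """The highest expenditure decile of a cohort."""

    n: int                 #: cohort size
    count: int             #: patients in the top decile, N - floor(0.9 N)
    threshold: float       #: smallest total inside the decile (EUR)
    share: float           #: decile spending / total spending


def top_decile_summary(totals: pd.Series) -> DecileSummary:
    """Size, entry threshold and spending share of the top spending decile.

    ``totals`` holds one 12-month total per cohort patient, indexed by
    patient id, zeros included.  The decile contains the
    ``N - floor(0.9 N)`` highest totals; ties at the boundary are broken
    by a stable rank on patient id.
    """
    if len(totals) == 0:
        raise ValueError("patient totals are empty")
    n = len(totals)
    count = n - int(np.floor(0.9 * n))
    ordered = totals.sort_index(kind="stable").sort_values(kind="stable")
    top = ordered.iloc[n - count:]
    grand = float(totals.sum())
    return DecileSummary(
        n=n,
        count=count,
        threshold=float(top.iloc[0]),
        share=float(top.sum()) / grand if grand else 0.0,
    )


def cluster_cost_summary(labels: pd.Series, totals: pd.Series) -> pd.DataFrame:
    """Per-cluster summary of patient 12-month totals.

    Returns one row per cluster: n, mean, sd, median, iqr (width).
    ``labels`` maps patient id to cluster; every patient in ``totals``
    must be labelled.
    """
    labels = pd.Series(labels)
    missing = totals.index.difference(labels.index)
    if len(missing):
        raise ValueError(f"unlabelled patients in totals: {list(missing[:5])}")
    rows = []
    for c in sorted(labels.unique()):
        members = labels.index[labels == c].intersection(totals.index)
        if len(members) == 0:
            warnings.warn(f"cluster {c} has no patients with totals; excluded")
            continue
        v = totals.loc[members].to_numpy(dtype=float)
        rows.append(
            {
                "cluster": c,
                "n": len(v),
                "mean": float(v.mean()),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                "median": float(np.median(v)),
                "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def cluster_cost_share(sizes, means) -> np.ndarray:
    """Each cluster's share of total spending from its size and mean cost.

    share_k = n_k * mean_k / sum_j n_j * mean_j.
    """
    sizes = np.asarray(sizes, dtype=float)
    means = np.asarray(means, dtype=float)
    if sizes.shape != means.shape:
        raise ValueError("sizes and means must align")
    if np.any(sizes < 0) or np.any(means < 0):
        raise ValueError("sizes and means must be non-negative")
    prod = sizes * means
    total = prod.sum()
    if total == 0:
        raise ValueError("total cost is zero; shares undefined")
    return prod / total
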