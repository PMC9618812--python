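"""Cohort accounting: response classification, rates and a baseline table.

Response labels follow the evaluable-denominator logic used in the
clinical analysis this package models:

* **responder** — complete remission (CR) together with bone-marrow
  undetectable minimal residual disease (BM uMRD);
* **non-responder** — no-CR (marrow data not required: failing CR alone
  suffices), or CR with detectable BM MRD;
* **unclassifiable** — CR status missing, or CR with missing marrow data.

Each outcome's percentage is computed over the patients actually
evaluable for that outcome, so CR, blood-MRD, BM-MRD and combined
responder rates legitimately carry different denominators.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import ClinicalTable

__all__ = [
    "ResponseSummary",
    "classify_response",
    "rate",
    "median_iqr",
    "baseline_table",
]


@dataclasses.dataclass
class ResponseSummary:
    """Numerators, evaluable denominators and rounded percentages per outcome."""

    table: pd.DataFrame  # index outcome; columns numerator, denominator, percent
    by_arm: pd.DataFrame | None = None

    def percent(self, outcome: str) -> float:
        return float(self.table.loc[outcome, "percent"])


def rate(numerator: int, denominator: int) -> float:
    """Percentage 100*num/den, rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise ValueError("rate requires a positive denominator")
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _classify_row(cr, bm) -> str:
    if pd.isna(cr):
        return "unclassifiable"
    if cr == "no-CR":
        return "non-responder"
    # cr == "CR"
    if pd.isna(bm):
        return "unclassifiable"
    return "responder" if bm == "uMRD" else "non-responder"


def classify_response(
    clinical: ClinicalTable,
) -> tuple[pd.Series, ResponseSummary]:
    """Per-patient responder category plus the outcome rate summary.

    Returns ``(categories, summary)`` where ``categories`` is a Series in
    {responder, non-responder, unclassifiable} indexed by patient and
    ``summary`` tabulates CR, blood-uMRD, BM-uMRD and combined responder
    rates over their own evaluable denominators.
    """
    df = clinical.data
    cats = pd.Series(
        [_classify_row(cr, bm) for cr, bm in zip(df["cr"], df["bm_mrd"])],
        index=df.index,
        name="response_category",
    )

    def _row(num: int, den: int) -> dict:
        return {
            "numerator": num,
            "denominator": den,
            "percent": rate(num, den) if den else float("nan"),
        }

    # CR rates follow the printed-arithmetic convention of the modeled
    # study: the denominator is the full cohort, even when some patients
    # lack a CR assessment. MRD and responder rates use the per-outcome
    # evaluable denominators.
    blood_known = df["blood_mrd"].notna()
    bm_known = df["bm_mrd"].notna()
    classifiable = cats != "unclassifiable"
    table = pd.DataFrame(
        {
            "CR": _row(int((df["cr"] == "CR").sum()), len(df)),
            "no-CR": _row(int((df["cr"] == "no-CR").sum()), len(df)),
            "blood-uMRD": _row(
                int((df["blood_mrd"] == "uMRD").sum()), int(blood_known.sum())
            ),
            "BM-uMRD": _row(int((df["bm_mrd"] == "uMRD").sum()), int(bm_known.sum())),
            "responder": _row(int((cats == "responder").sum()), int(classifiable.sum())),
            "non-responder": _row(
                int((cats == "non-responder").sum()), int(classifiable.sum())
            ),
        }
    ).T
    table["numerator"] = table["numerator"].astype(int)
    table["denominator"] = table["denominator"].astype(int)

    by_arm = None
    if "arm" in df.columns:
        rows = {}
        for arm, sub in df.groupby("arm"):
            sub_cat = cats[sub.index]
            cls = sub_cat != "unclassifiable"
            rows[arm] = {
                "n": len(sub),
                "responders": int((sub_cat == "responder").sum()),
                "classifiable": int(cls.sum()),
                "responder_percent": (
                    rate(int((sub_cat == "responder").sum()), int(cls.sum()))
                    if cls.any()
                    else float("nan")
                ),
            }
        by_arm = pd.DataFrame(rows).T

    return cats, ResponseSummary(table, by_arm)


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles (linear-interpolation / type-7 convention)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("median_iqr requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


_CATEGORICAL_ROWS = [
    ("Women", "sex", "F"),
    ("Binet stage AB", "binet", "AB"),
    ("Unmutated IGHV", "ighv", "unmutated"),
    ("Del(13q)", "del13q", "yes"),
    ("Del(11q)", "del11q", "yes"),
    ("Trisomy 12", "tri12", "yes"),
    ("Treatment arm FCR", "arm", "FCR"),
]
_NUMERIC_ROWS = [
    ("Age (years)", "age"),
    ("Lymphocyte count (G/L)", "lymphocytes"),
    ("B2 microglobulin (mg/L)", "b2m"),
]


def baseline_table(clinical: ClinicalTable) -> pd.DataFrame:
    """Baseline-characteristics summary: n/denominator (%) and median (IQR).

    Categorical rows report counts over the per-variable evaluable
    denominator; numeric rows report median and interquartile range.
    """
    df = clinical.data
    rows = []
    for label, col, level in _CATEGORICAL_ROWS:
        if col not in df.columns:
            continue
        known = df[col].notna()
        num, den = int((df[col] == level).sum()), int(known.sum())
        rows.append(
            {
                "characteristic": label,
                "n": num,
                "denominator": den,
                "percent": rate(num, den) if den else float("nan"),
                "display": f"{num}/{den} ({rate(num, den):.2f})" if den else "",
            }
        )
    for label, col in _NUMERIC_ROWS:
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        if vals.empty:
            continue
        med, q1, q3 = median_iqr(vals)
        rows.append(
            {
                "characteristic": label,
                "n": len(vals),
                "denominator": len(vals),
                "percent": float("nan"),
                "display": f"{med:.2f} ({q1:.2f}-{q3:.2f})",
            }
        )
    return pd.DataFrame(rows).set_index("characteristic")
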