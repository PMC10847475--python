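"""Cohort descriptive statistics and diagnostic yield.

Summarizes a per-proband record table into counts and percentages of the
kind reported in a clinical cohort table: sex, vertebral malformation class
(failure of formation / segmentation defect / mixed), intraspinal and
multi-systemic anomaly categories, and the molecular diagnostic yield.
Percentages are rounded half-up to one decimal, matching clinical-table
convention.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

__all__ = [
    "MALFORMATION_CLASSES",
    "read_proband_table",
    "percentage",
    "summarize_cohort",
]

MALFORMATION_CLASSES = ["failure_of_formation", "segmentation_defect", "mixed"]

_REQUIRED = ["proband_id", "sex", "malformation_class", "diagnosed"]

_TRUE = {"1", "true", "yes", "y", "t"}


def percentage(count: int, total: int) -> float:
    """count / total x 100, rounded half-up to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def read_proband_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    bad = ~df["malformation_class"].isin(MALFORMATION_CLASSES)
    if bad.any():
        value = df.loc[bad, "malformation_class"].iloc[0]
        raise ValueError(f"unknown malformation_class {value!r}")
    out = df.copy()
    out["diagnosed"] = df["diagnosed"].str.strip().str.lower().isin(_TRUE)
    if "age_at_diagnosis" in df.columns:
        out["age_at_diagnosis"] = pd.to_numeric(df["age_at_diagnosis"], errors="coerce")
    for col in df.columns:
        if col.startswith(("intraspinal_", "anomaly_")):
            out[col] = df[col].str.strip().str.lower().isin(_TRUE)
    return out


def summarize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category plus the diagnostic yield.

    Returns a tidy DataFrame with columns (section, category, count, pct).
    Boolean flag columns prefixed ``intraspinal_`` or ``anomaly_`` are
    summarized one row each; ``malformation_class`` and ``sex`` are expanded
    over their categories; the ``diagnosed`` flag becomes the
    ``diagnostic_yield`` section.
    """
    if records.empty:
        raise ValueError("proband table is empty")
    total = len(records)
    rows: list[tuple[str, str, int, float]] = [
        ("cohort", "n_probands", total, 100.0)
    ]
    for sex, count in records["sex"].value_counts().items():
        rows.append(("sex", str(sex), int(count), percentage(int(count), total)))
    for cls in MALFORMATION_CLASSES:
        count = int((records["malformation_class"] == cls).sum())
        rows.append(("malformation_class", cls, count, percentage(count, total)))
    for col in records.columns:
        if col.startswith("intraspinal_"):
            count = int(records[col].sum())
            rows.append(
                ("intraspinal_anomaly", col.removeprefix("intraspinal_"),
                 count, percentage(count, total))
            )
        elif col.startswith("anomaly_"):
            count = int(records[col].sum())
            rows.append(
                ("multisystem_anomaly", col.removeprefix("anomaly_"),
                 count, percentage(count, total))
            )
    diagnosed = int(records["diagnosed"].sum())
    rows.append(
        ("diagnostic_yield", "diagnosed", diagnosed, percentage(diagnosed, total))
    )
    return pd.DataFrame(rows, columns=["section", "category", "count", "pct"])
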