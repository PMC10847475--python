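"""Annotated-variant handling.

Reads per-variant annotation tables (TSV, or VCF sites + TSV annotation),
reduces multi-transcript annotations to one canonical row per (variant, gene),
applies the ultra-rare-variant (URV) filter, and assigns each variant a
functional weight in [0, 1] from a configurable weight table.

A URV is a variant with gnomAD control population-max allele frequency
(popmax AF) <= 0.01% and a cohort allele count (AC) <= 3; both thresholds are
inclusive and configurable.  A variant is "qualified" when its assigned
weight is nonzero.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VARIANT_COLUMNS",
    "CONSEQUENCE_CLASSES",
    "CONSEQUENCE_SEVERITY",
    "VariantFormatError",
    "read_variant_table",
    "write_variant_table",
    "read_vcf_genotypes",
    "read_carrier_table",
    "read_label_table",
    "select_canonical",
    "compute_cohort_ac",
    "filter_urv",
    "WeightTable",
    "FUNCTIONAL_WEIGHTS",
    "SYNONYMOUS_CALIBRATION_WEIGHTS",
    "assign_weights",
]

# Exact TSV header of the annotated variant table.  ``cohort_ac`` may be
# absent, in which case it is computed from the carrier table.
VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "canonical",
    "consequence",
    "damaging_prediction_count",
    "gnomad_popmax_af",
    "cohort_ac",
]

CONSEQUENCE_CLASSES = ["pLoF", "inframe_indel", "missense", "synonymous", "other"]

# Lower rank = more severe; used as the fallback tie-break when no
# transcript carries a canonical flag.
CONSEQUENCE_SEVERITY = {c: i for i, c in enumerate(CONSEQUENCE_CLASSES)}

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}
_FALSE_STRINGS = {"0", "false", "no", "n", "f", ""}


class VariantFormatError(ValueError):
    """Raised when a variant, carrier, or label table cannot be parsed."""


def _parse_bool_column(series: pd.Series, column: str) -> pd.Series:
    lowered = series.astype(str).str.strip().str.lower()
    bad = ~lowered.isin(_TRUE_STRINGS | _FALSE_STRINGS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise VariantFormatError(
            f"column {column!r}: unparseable boolean {series.iloc[row]!r} "
            f"at data row {row + 1}"
        )
    return lowered.isin(_TRUE_STRINGS)


def _parse_numeric_column(
    series: pd.Series, column: str, *, integer: bool, missing_as: float | None
) -> pd.Series:
    raw = series.astype(str).str.strip()
    values = pd.to_numeric(raw.replace({"": None, ".": None, "NA": None}), errors="coerce")
    missing_input = raw.isin(["", ".", "NA"]) | series.isna()
    bad = values.isna() & ~missing_input
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise VariantFormatError(
            f"column {column!r}: unparseable value {series.iloc[row]!r} "
            f"at data row {row + 1}"
        )
    if missing_input.any():
        if missing_as is None:
            row = int(np.flatnonzero(missing_input.to_numpy())[0])
            raise VariantFormatError(
                f"column {column!r}: missing value at data row {row + 1}"
            )
        values = values.fillna(missing_as)
    if integer:
        if not np.allclose(values, np.round(values)):
            row = int(np.flatnonzero(~np.isclose(values, np.round(values)))[0])
            raise VariantFormatError(
                f"column {column!r}: non-integer value {series.iloc[row]!r} "
                f"at data row {row + 1}"
            )
        return values.astype(int)
    return values.astype(float)


def read_variant_table(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read an annotated variant TSV into a typed DataFrame.

    Missing ``gnomad_popmax_af`` entries (empty, ".", "NA") are treated as 0:
    a variant absent from gnomAD is novel, hence maximally rare.  The
    ``cohort_ac`` column is optional; when absent it must later be supplied
    by :func:`compute_cohort_ac`.

    Raises
    ------
    VariantFormatError
        If a required column is missing or a required field cannot be parsed
        (the error names the column and 1-based data row).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [c for c in VARIANT_COLUMNS if c != "cohort_ac"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VariantFormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        out = pd.DataFrame(columns=VARIANT_COLUMNS)
        return out.astype({"pos": int, "canonical": bool,
                           "damaging_prediction_count": int,
                           "gnomad_popmax_af": float, "cohort_ac": float})
    out = df.copy()
    out["pos"] = _parse_numeric_column(df["pos"], "pos", integer=True, missing_as=None)
    out["canonical"] = _parse_bool_column(df["canonical"], "canonical")
    out["damaging_prediction_count"] = _parse_numeric_column(
        df["damaging_prediction_count"], "damaging_prediction_count",
        integer=True, missing_as=0,
    )
    out["gnomad_popmax_af"] = _parse_numeric_column(
        df["gnomad_popmax_af"], "gnomad_popmax_af", integer=False, missing_as=0.0
    )
    if "cohort_ac" in df.columns:
        out["cohort_ac"] = _parse_numeric_column(
            df["cohort_ac"], "cohort_ac", integer=True, missing_as=None
        )
    bad_conseq = ~out["consequence"].isin(CONSEQUENCE_CLASSES)
    if bad_conseq.any():
        row = int(np.flatnonzero(bad_conseq.to_numpy())[0])
        raise VariantFormatError(
            f"column 'consequence': unknown class "
            f"{out['consequence'].iloc[row]!r} at data row {row + 1}"
        )
    bad_af = (out["gnomad_popmax_af"] < 0) | (out["gnomad_popmax_af"] > 1)
    if bad_af.any():
        row = int(np.flatnonzero(bad_af.to_numpy())[0])
        raise VariantFormatError(
            f"column 'gnomad_popmax_af': frequency outside [0, 1] "
            f"at data row {row + 1}"
        )
    return out[[c for c in VARIANT_COLUMNS if c in out.columns]]


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_carrier_table(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a long carrier TSV with columns (variant_id, sample_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("variant_id", "sample_id") if c not in df.columns]
    if missing:
        raise VariantFormatError(f"missing required column(s): {', '.join(missing)}")
    return df[["variant_id", "sample_id"]]


def read_label_table(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a sample label TSV with columns (sample_id, status in {case, control})."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("sample_id", "status") if c not in df.columns]
    if missing:
        raise VariantFormatError(f"missing required column(s): {', '.join(missing)}")
    bad = ~df["status"].isin(["case", "control"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise VariantFormatError(
            f"column 'status': expected 'case' or 'control', got "
            f"{df['status'].iloc[row]!r} at data row {row + 1}"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise VariantFormatError(f"duplicated sample_id {dup!r} in label table")
    return df[["sample_id", "status"]]


def read_vcf_genotypes(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF (v4.x) and return (sites, carriers).

    Multi-allelic records are split into one biallelic record per ALT allele.
    ``variant_id`` is ``chrom-pos-ref-alt`` (1-based position).  A sample is a
    carrier of an allele when its genotype contains that allele at least once
    (het and hom are both carriers).

    Returns
    -------
    sites : DataFrame with columns variant_id, chrom, pos, ref, alt, cohort_ac
        cohort_ac is the allele count over all samples in the file.
    carriers : DataFrame with columns variant_id, sample_id
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    site_rows: list[tuple] = []
    carrier_rows: list[tuple[str, str]] = []
    for rec in vcf:
        genotypes = rec.genotype.array()[:, :-1] if rec.genotype is not None else None
        for alt_index, alt in enumerate(rec.ALT, start=1):
            vid = f"{rec.CHROM}-{rec.POS}-{rec.REF}-{alt}"
            ac = 0
            if genotypes is not None:
                hits = genotypes == alt_index
                ac = int(hits.sum())
                for sample_index in np.flatnonzero(hits.any(axis=1)):
                    carrier_rows.append((vid, samples[sample_index]))
            site_rows.append((vid, rec.CHROM, rec.POS, rec.REF, alt, ac))
    sites = pd.DataFrame(
        site_rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "cohort_ac"]
    )
    carriers = pd.DataFrame(carrier_rows, columns=["variant_id", "sample_id"])
    return sites, carriers


def select_canonical(variants: pd.DataFrame) -> pd.DataFrame:
    """Reduce annotations to one row per (variant_id, gene).

    The canonical-flagged transcript is chosen when present.  Ties among
    several canonical rows go to the lexicographically smallest transcript
    identifier; when no row is flagged canonical, the most severe consequence
    wins (pLoF > inframe_indel > missense > synonymous > other), then the
    smallest transcript identifier.
    """
    if variants.empty:
        return variants.copy()
    ranked = variants.assign(
        _noncanon=~variants["canonical"].astype(bool),
        _severity=variants["consequence"].map(CONSEQUENCE_SEVERITY),
    )
    ranked = ranked.sort_values(
        ["variant_id", "gene", "_noncanon", "_severity", "transcript"],
        kind="mergesort",
    )
    out = ranked.drop_duplicates(["variant_id", "gene"], keep="first")
    return out.drop(columns=["_noncanon", "_severity"]).reset_index(drop=True)


def compute_cohort_ac(variants: pd.DataFrame, carriers: pd.DataFrame) -> pd.DataFrame:
    """Fill/overwrite ``cohort_ac`` with carrier counts from the carrier table.

    Carrier status is binary per sample, so the allele count equals the
    number of carrier samples (heterozygous convention).
    """
    counts = carriers.groupby("variant_id")["sample_id"].nunique()
    out = variants.copy()
    out["cohort_ac"] = out["variant_id"].map(counts).fillna(0).astype(int)
    return out


def filter_urv(
    variants: pd.DataFrame, popmax_max: float = 1e-4, ac_max: int = 3
) -> pd.DataFrame:
    """Retain ultra-rare variants: popmax AF <= popmax_max and AC <= ac_max.

    Both thresholds are inclusive; the operation is idempotent.  Missing
    popmax AF must already be encoded as 0 (see :func:`read_variant_table`).
    """
    if popmax_max < 0 or ac_max < 0:
        raise ValueError("URV thresholds must be nonnegative")
    if "cohort_ac" not in variants.columns:
        raise VariantFormatError(
            "cohort_ac column required for URV filtering; "
            "compute it with compute_cohort_ac"
        )
    keep = (variants["gnomad_popmax_af"] <= popmax_max) & (
        variants["cohort_ac"] <= ac_max
    )
    return variants.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class WeightTable:
    """Maps (consequence class, damaging-prediction tier) to a weight in [0, 1].

    ``weights`` gives one weight per non-missense class; missense weights are
    tiered on the number of in-silico damaging predictions through
    ``missense_tiers``, a list of (min_predictions, weight) pairs — the tier
    with the largest ``min_predictions`` not exceeding the variant's count
    applies.  A plain ``missense`` entry in ``weights`` acts as a single flat
    tier.
    """

    name: str
    weights: dict[str, float]
    missense_tiers: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for cls, w in self.weights.items():
            if not 0.0 <= float(w) <= 1.0:
                raise ValueError(f"weight for {cls!r} outside [0, 1]: {w}")
        for _, w in self.missense_tiers:
            if not 0.0 <= float(w) <= 1.0:
                raise ValueError(f"missense tier weight outside [0, 1]: {w}")
        object.__setattr__(
            self,
            "missense_tiers",
            tuple(sorted(((int(k), float(w)) for k, w in self.missense_tiers),
                         reverse=True)),
        )

    def weight(self, consequence: str, damaging_prediction_count: int = 0) -> float:
        if consequence == "missense" and self.missense_tiers:
            for min_pred, w in self.missense_tiers:
                if damaging_prediction_count >= min_pred:
                    return float(w)
            # tiers exist but none matched (count below the lowest tier)
            return float(self.weights.get("missense", 0.0))
        if consequence not in self.weights:
            raise KeyError(
                f"weight table {self.name!r} has no entry for consequence "
                f"class {consequence!r}"
            )
        return float(self.weights[consequence])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WeightTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        tiers = tuple(
            (int(t["min_predictions"]), float(t["weight"]))
            for t in doc.get("missense_tiers", [])
        )
        return cls(
            name=str(doc.get("name", Path(path).stem)),
            weights={str(k): float(v) for k, v in doc.get("weights", {}).items()},
            missense_tiers=tiers,
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "name": self.name,
            "weights": {k: float(v) for k, v in self.weights.items()},
            "missense_tiers": [
                {"min_predictions": k, "weight": w} for k, w in self.missense_tiers
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# Default table for the functional (main) analysis: predicted loss-of-function
# variants carry full weight, in-frame indels and strongly supported missense
# 0.8, weakly supported missense less, synonymous and other classes 0.
FUNCTIONAL_WEIGHTS = WeightTable(
    name="functional",
    weights={"pLoF": 1.0, "inframe_indel": 0.8, "synonymous": 0.0, "other": 0.0},
    missense_tiers=((2, 0.8), (1, 0.5), (0, 0.2)),
)

# Negative-control table: only synonymous variants carry weight.  Running the
# burden pipeline under this table is the standard empirical-calibration check.
SYNONYMOUS_CALIBRATION_WEIGHTS = WeightTable(
    name="synonymous_calibration",
    weights={"pLoF": 0.0, "inframe_indel": 0.0, "missense": 0.0,
             "synonymous": 1.0, "other": 0.0},
)

BUILTIN_WEIGHT_TABLES = {
    "functional": FUNCTIONAL_WEIGHTS,
    "synonymous_calibration": SYNONYMOUS_CALIBRATION_WEIGHTS,
}


def assign_weights(variants: pd.DataFrame, table: WeightTable) -> pd.DataFrame:
    """Annotate each variant with its weight; qualified means weight != 0."""
    if variants.empty:
        out = variants.copy()
        out["weight"] = pd.Series(dtype=float)
        return out
    conseq = variants["consequence"]
    counts = variants["damaging_prediction_count"].to_numpy()
    known = set(table.weights) | ({"missense"} if table.missense_tiers else set())
    unknown = set(conseq.unique()) - known
    if unknown:
        raise KeyError(
            f"weight table {table.name!r} has no entry for consequence "
            f"class {sorted(unknown)[0]!r}"
        )
    weights = conseq.map({k: float(v) for k, v in table.weights.items()}).to_numpy(
        dtype=float, na_value=0.0
    )
    if table.missense_tiers:
        is_mis = (conseq == "missense").to_numpy()
        tier_w = np.full(len(variants), table.weights.get("missense", 0.0))
        # tiers are sorted by descending min_predictions; apply lowest first
        for min_pred, w in reversed(table.missense_tiers):
            tier_w = np.where(counts >= min_pred, w, tier_w)
        weights = np.where(is_mis, tier_w, weights)
    out = variants.copy()
    out["weight"] = weights
    return out
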