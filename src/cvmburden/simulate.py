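"""Synthetic case-control cohorts, gene sets, and single-cell matrices.

Every downstream stage of the pipeline is exercised on generated data with a
known ground truth: a case-control ultra-rare-variant cohort with planted
risk genes at configurable carrier odds ratios, GMT gene sets with an
optional planted set, and a labeled single-nucleus-style count matrix with
gene sets planted at a fold-change in one cell type.

Risk is simulated at the gene level: each sample carries at most one
aggregated qualifying-variant indicator per gene, redistributed uniformly
over the gene's qualifying variants.  For a risk gene with carrier odds
ratio R and control carrier probability p0, cases carry with probability
p1 = R * p0 / (1 - p0 + R * p0).

Default cohort dimensions mirror a burden study of ~750 undiagnosed cases
against ~3740 sequenced controls, with thousands of genes each carrying tens
of ultra-rare variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .variants import FUNCTIONAL_WEIGHTS, VARIANT_COLUMNS, assign_weights

__all__ = [
    "SimulationConfig",
    "ExpressionSimConfig",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_expression",
    "simulate_genesets",
    "gene_carrier_prob",
    "case_carrier_prob",
    "write_gmt",
    "write_expression_mtx",
]

_BASES = np.array(list("ACGT"))

# Damaging-prediction-count distribution for simulated missense variants
# (counts 0..3); all tiers carry nonzero weight under the functional table.
_MISSENSE_PRED_PROBS = (0.40, 0.25, 0.20, 0.15)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the case-control ultra-rare-variant cohort generator.

    ``popmax_af_model`` is a mixture: with probability ``p_zero`` the variant
    is novel (popmax AF = 0); otherwise the AF is log-uniform between
    ``10**log10_min`` and ``10**log10_max``, putting mass on both sides of
    the 1e-4 ultra-rare threshold.

    ``carrier_freq_per_variant`` is the per-qualifying-variant carrier
    probability; the gene-level carrier probability is
    1 - (1 - f)**n_qualifying (about 0.01 under the defaults).

    ``max_ac_per_variant`` caps the allele count of each qualifying variant
    when gene-level carriers are redistributed: ultra-rare variants are
    near-singletons by definition, so a generator of URV cohorts keeps
    per-variant allele counts at or below the URV allele-count limit
    (carriers overflow the cap only when a gene's carriers exceed the total
    capacity of its qualifying variants).
    """

    n_cases: int = 744
    n_controls: int = 3740
    n_genes: int = 2000
    variants_per_gene_mean: float = 60.0
    consequence_class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "pLoF": 0.08,
            "inframe_indel": 0.04,
            "missense": 0.48,
            "synonymous": 0.28,
            "other": 0.12,
        }
    )
    popmax_af_model: Mapping[str, float] = field(
        default_factory=lambda: {"p_zero": 0.5, "log10_min": -7.0, "log10_max": -2.0}
    )
    carrier_freq_per_variant: float = 3.2e-4
    max_ac_per_variant: int = 3
    risk_genes: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.variants_per_gene_mean <= 0:
            raise ConfigurationError("variants_per_gene_mean must be positive")
        total = float(sum(self.consequence_class_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"consequence proportions must sum to 1, got {total}"
            )
        if any(v < 0 for v in self.consequence_class_proportions.values()):
            raise ConfigurationError("consequence proportions must be nonnegative")
        if not 0 < self.carrier_freq_per_variant < 1:
            raise ConfigurationError("carrier_freq_per_variant must be in (0, 1)")
        pz = self.popmax_af_model.get("p_zero", 0.0)
        if not 0 <= pz <= 1:
            raise ConfigurationError("popmax_af_model p_zero must be in [0, 1]")
        for gene, oddsratio in self.risk_genes:
            if oddsratio <= 0:
                raise ConfigurationError(f"odds ratio for {gene!r} must be > 0")
        object.__setattr__(self, "risk_genes", tuple(self.risk_genes))

    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]


def gene_carrier_prob(config: SimulationConfig, n_qualifying: int) -> float:
    """Gene-level control carrier probability implied by the config."""
    return 1.0 - (1.0 - config.carrier_freq_per_variant) ** n_qualifying


def case_carrier_prob(p0: float, oddsratio: float) -> float:
    """Case carrier probability for control probability p0 at a carrier OR."""
    return oddsratio * p0 / (1.0 - p0 + oddsratio * p0)


def _simulate_variant_annotations(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    genes = config.gene_names()
    n_var = np.maximum(1, rng.poisson(config.variants_per_gene_mean, config.n_genes))
    total = int(n_var.sum())
    gene_idx = np.repeat(np.arange(config.n_genes), n_var)
    # one gene per locus: positions unique within a chromosome by construction
    chrom = (gene_idx % 22) + 1
    offset = np.concatenate([np.arange(1, k + 1) for k in n_var])
    pos = gene_idx * 100_000 + offset * 3 + 1
    ref = _BASES[rng.integers(0, 4, total)]
    alt = _BASES[(np.char.find("ACGT", ref.astype(str)) + rng.integers(1, 4, total)) % 4]
    classes = list(config.consequence_class_proportions)
    probs = np.array([config.consequence_class_proportions[c] for c in classes])
    consequence = np.array(classes, dtype=object)[
        rng.choice(len(classes), size=total, p=probs / probs.sum())
    ]
    pred = np.zeros(total, dtype=int)
    mis = consequence == "missense"
    pred[mis] = rng.choice(4, size=int(mis.sum()), p=_MISSENSE_PRED_PROBS)
    model = config.popmax_af_model
    novel = rng.random(total) < model.get("p_zero", 0.5)
    log10af = rng.uniform(model["log10_min"], model["log10_max"], total)
    popmax = np.where(novel, 0.0, 10.0 ** log10af)
    df = pd.DataFrame(
        {
            "variant_id": [
                f"{c}-{p}-{r}-{a}" for c, p, r, a in zip(chrom, pos, ref, alt)
            ],
            "chrom": chrom.astype(str),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene": np.array(genes, dtype=object)[gene_idx],
            "transcript": [f"ENST{i + 1:011d}" for i in range(total)],
            "canonical": True,
            "consequence": consequence,
            "damaging_prediction_count": pred,
            "gnomad_popmax_af": popmax,
        }
    )
    return df


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (variant table, carrier table, label table) for a cohort.

    The variant table has the standard annotation columns including
    ``cohort_ac`` (the realized carrier count, heterozygous convention).
    The carrier table is long (variant_id, sample_id); the label table maps
    sample_id to case/control.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    gene_set = set(genes)
    for gene, _ in config.risk_genes:
        if gene not in gene_set:
            raise ConfigurationError(f"risk gene {gene!r} not in simulated universe")

    variants = _simulate_variant_annotations(config, rng)

    # a variant "qualifies" for gene-level risk redistribution when it would
    # pass the popmax arm of the URV filter and carry nonzero functional weight
    weighted = assign_weights(variants, FUNCTIONAL_WEIGHTS)
    qualifies = (weighted["weight"].to_numpy() > 0) & (
        variants["gnomad_popmax_af"].to_numpy() <= 1e-4
    )

    n_samples = config.n_cases + config.n_controls
    sample_ids = np.array(
        [f"case{i:05d}" for i in range(1, config.n_cases + 1)]
        + [f"ctrl{i:05d}" for i in range(1, config.n_controls + 1)],
        dtype=object,
    )
    is_case = np.zeros(n_samples, dtype=bool)
    is_case[: config.n_cases] = True

    gene_idx_of_variant = variants["gene"].map(
        {g: i for i, g in enumerate(genes)}
    ).to_numpy()
    qual_counts = np.bincount(
        gene_idx_of_variant[qualifies], minlength=config.n_genes
    )
    p0 = 1.0 - (1.0 - config.carrier_freq_per_variant) ** qual_counts
    p_case = p0.copy()
    risk_map = dict(config.risk_genes)
    for j, g in enumerate(genes):
        if g in risk_map:
            p_case[j] = case_carrier_prob(p0[j], risk_map[g])

    # gene-level carrier indicators (samples x genes)
    u = rng.random((n_samples, config.n_genes))
    p_matrix = np.where(is_case[:, None], p_case[None, :], p0[None, :])
    carrier_mat = u < p_matrix

    # redistribute each gene-level carrier uniformly over qualifying variants
    rows_list: list[np.ndarray] = []  # variant row index in `variants`
    samp_list: list[np.ndarray] = []
    # variants are ordered by gene, so qualifying rows split contiguously
    qual_idx = np.flatnonzero(qualifies)
    bounds = np.searchsorted(gene_idx_of_variant[qual_idx],
                             np.arange(config.n_genes + 1))
    for j in range(config.n_genes):
        qual_rows = qual_idx[bounds[j]:bounds[j + 1]]
        if len(qual_rows) == 0:
            continue
        carriers_j = np.flatnonzero(carrier_mat[:, j])
        if len(carriers_j) == 0:
            continue
        # capacity-constrained uniform assignment: each qualifying variant
        # takes at most max_ac_per_variant carriers
        slots = np.repeat(qual_rows, config.max_ac_per_variant)
        rng.shuffle(slots)
        n_c = len(carriers_j)
        if n_c <= len(slots):
            pick = slots[:n_c]
        else:
            overflow = qual_rows[rng.integers(0, len(qual_rows), n_c - len(slots))]
            pick = np.concatenate([slots, overflow])
        rows_list.append(pick)
        samp_list.append(carriers_j)

    # non-qualifying variants receive independent background carriers at the
    # per-variant rate (they are removed by filtering/weighting downstream)
    nonqual_rows = np.flatnonzero(~qualifies)
    bg_counts = rng.binomial(n_samples, config.carrier_freq_per_variant,
                             len(nonqual_rows))
    repeat_rows = np.repeat(nonqual_rows, bg_counts)
    bg_samples = rng.integers(0, n_samples, len(repeat_rows))
    if len(repeat_rows):
        pair = np.unique(
            np.stack([repeat_rows, bg_samples], axis=1), axis=0
        )  # drop duplicate (variant, sample) pairs from with-replacement draw
        rows_list.append(pair[:, 0])
        samp_list.append(pair[:, 1])

    if rows_list:
        all_rows = np.concatenate(rows_list)
        all_samps = np.concatenate(samp_list)
    else:
        all_rows = np.zeros(0, dtype=int)
        all_samps = np.zeros(0, dtype=int)
    carriers = pd.DataFrame(
        {
            "variant_id": variants["variant_id"].to_numpy()[all_rows],
            "sample_id": sample_ids[all_samps],
        }
    ).sort_values(["variant_id", "sample_id"], kind="mergesort").reset_index(drop=True)

    ac = carriers.groupby("variant_id").size()
    variants["cohort_ac"] = (
        variants["variant_id"].map(ac).fillna(0).astype(int)
    )
    variants = variants[VARIANT_COLUMNS]

    labels = pd.DataFrame(
        {"sample_id": sample_ids, "status": np.where(is_case, "case", "control")}
    )
    return variants, carriers, labels


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Knobs of the labeled single-cell count-matrix generator.

    Counts are negative-binomial with mean ``baseline_mean`` and dispersion
    theta (variance = mu + mu**2 / theta).  Each planted set
    (genes, cell type, fold) multiplies the mean of its genes by ``fold`` in
    the target cell type only, at every stage.
    """

    n_genes: int = 2000
    cell_types: tuple[str, ...] = tuple(f"CT{i:02d}" for i in range(1, 13))
    stages: tuple[str, ...] = ("5w", "6w", "7w", "8w", "17w")
    cells_per_type_stage: int = 200
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    planted_sets: tuple[tuple[tuple[str, ...], str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.cells_per_type_stage <= 0:
            raise ConfigurationError("counts must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigurationError("baseline_mean and dispersion must be positive")
        if len(self.cell_types) < 2:
            raise ConfigurationError("need at least two cell types")
        genes = set(self.gene_names())
        for members, cell_type, fold in self.planted_sets:
            if fold < 1:
                raise ConfigurationError("planted fold factor must be >= 1")
            if cell_type not in self.cell_types:
                raise ConfigurationError(f"unknown target cell type {cell_type!r}")
            missing = set(members) - genes
            if missing:
                raise ConfigurationError(
                    f"planted set references unknown gene {sorted(missing)[0]!r}"
                )
        object.__setattr__(
            self,
            "planted_sets",
            tuple((tuple(m), ct, float(f)) for m, ct, f in self.planted_sets),
        )
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        object.__setattr__(self, "stages", tuple(self.stages))

    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[sparse.csr_matrix, list[str], pd.DataFrame]:
    """Generate (counts, genes, cell metadata) for a labeled cell atlas.

    Returns a genes x cells sparse count matrix, the gene symbols (rows),
    and a cell metadata DataFrame (cell_id, cell_type, stage).  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    theta = config.dispersion

    mean_by_type = np.full(
        (config.n_genes, len(config.cell_types)), config.baseline_mean
    )
    for members, cell_type, fold in config.planted_sets:
        t = config.cell_types.index(cell_type)
        rows = [gene_index[g] for g in members]
        mean_by_type[rows, t] *= fold

    blocks: list[sparse.csr_matrix] = []
    meta_rows: list[tuple[str, str, str]] = []
    cell_counter = 0
    for stage in config.stages:
        for t, cell_type in enumerate(config.cell_types):
            mu = np.repeat(
                mean_by_type[:, t][:, None], config.cells_per_type_stage, axis=1
            )
            counts = rng.negative_binomial(theta, theta / (theta + mu))
            blocks.append(sparse.csr_matrix(counts))
            for _ in range(config.cells_per_type_stage):
                cell_counter += 1
                meta_rows.append((f"cell{cell_counter:06d}", cell_type, stage))
    matrix = sparse.hstack(blocks, format="csr")
    meta = pd.DataFrame(meta_rows, columns=["cell_id", "cell_type", "stage"])
    return matrix, genes, meta


def simulate_genesets(
    n_sets: int,
    set_size: int,
    universe: Sequence[str],
    planted: Sequence[str] | None = None,
    seed: int = 0,
) -> list[tuple[str, str, list[str]]]:
    """Random gene sets as GMT records (set id, description, members).

    Sets are uniform draws without replacement from the universe; when
    ``planted`` is given, the first record equals it verbatim.
    """
    universe = list(universe)
    if not universe:
        raise ConfigurationError("gene universe is empty")
    if set_size > len(universe):
        raise ConfigurationError("set_size exceeds universe size")
    if n_sets < 1:
        raise ConfigurationError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, list[str]]] = []
    start = 1
    if planted is not None:
        records.append(("SET0001", "planted", list(planted)))
        start = 2
    for i in range(start, n_sets + 1):
        members = list(rng.choice(universe, size=set_size, replace=False))
        records.append((f"SET{i:04d}", "random", members))
    return records


def write_gmt(records: Sequence[tuple[str, str, Sequence[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, desc, members in records:
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def write_expression_mtx(
    matrix: sparse.spmatrix,
    genes: Sequence[str],
    cells: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """Write counts as MatrixMarket plus genes.tsv and cells.tsv sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(matrix))
    pd.Series(list(genes), name="gene").to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
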