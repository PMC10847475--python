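"""Expression-weighted cell-type enrichment (EWCE-style bootstrap).

From labeled single-cell counts, a per-stage specificity matrix is built:
for each gene, mean depth-normalized expression per cell type divided by the
sum of those means across the stage's cell types, so each expressed gene's
specificities sum to 1 within a stage.  A target gene set's aggregate
specificity in each (cell type, stage) group is then compared with the sums
of equally sized random background gene sets: z scores the observed sum in
bootstrap standard deviations from the bootstrap mean, and the one-sided
bootstrap p carries an add-one correction so it is never zero.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread

__all__ = [
    "read_expression_mtx",
    "compute_specificity",
    "specificity_all_stages",
    "ewce_bootstrap",
]


def read_expression_mtx(indir: str | Path) -> tuple[sparse.csr_matrix, list[str], pd.DataFrame]:
    """Read a MatrixMarket bundle (matrix.mtx, genes.tsv, cells.tsv)."""
    indir = Path(indir)
    matrix = sparse.csr_matrix(mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", dtype=str)
    required = {"cell_id", "cell_type", "stage"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells.tsv missing column(s): {', '.join(sorted(missing))}")
    if matrix.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    return matrix, genes, cells


def compute_specificity(
    counts: sparse.spmatrix | np.ndarray,
    genes: Sequence[str],
    cells: pd.DataFrame,
    stage: str,
) -> pd.DataFrame:
    """Per-gene cell-type specificity within one developmental stage.

    Counts are depth-normalized per cell (count / cell total x median cell
    total over the stage), averaged per cell type, and each gene's means are
    divided by their sum across the stage's cell types.  Genes with zero
    total mean in the stage are dropped (they carry no specificity signal
    and must not enter bootstrap backgrounds).

    Returns a genes x cell-types DataFrame whose rows sum to 1.
    """
    cells = cells.reset_index(drop=True)
    in_stage = cells.index[cells["stage"] == stage].to_numpy()
    if len(in_stage) == 0:
        raise ValueError(f"no cells in stage {stage!r}")
    types = sorted(cells.loc[in_stage, "cell_type"].unique())
    if len(types) < 2:
        raise ValueError(f"stage {stage!r} has fewer than two cell types")
    X = counts.tocsc()[:, in_stage] if sparse.issparse(counts) else np.asarray(counts)[:, in_stage]
    totals = np.asarray(X.sum(axis=0)).ravel().astype(float)
    totals[totals == 0] = 1.0  # empty cells contribute zeros either way
    scale = np.median(totals) / totals
    if sparse.issparse(X):
        X = X.multiply(sparse.csr_matrix(scale[None, :])).tocsc()
    else:
        X = X * scale[None, :]
    stage_types = cells.loc[in_stage, "cell_type"].to_numpy()
    means = np.empty((X.shape[0], len(types)))
    for t, cell_type in enumerate(types):
        cols = np.flatnonzero(stage_types == cell_type)
        sub = X[:, cols]
        means[:, t] = np.asarray(sub.mean(axis=1)).ravel()
    row_sum = means.sum(axis=1)
    expressed = row_sum > 0
    spec = means[expressed] / row_sum[expressed, None]
    return pd.DataFrame(
        spec, index=np.asarray(list(genes), dtype=object)[expressed], columns=types
    )


def specificity_all_stages(
    counts: sparse.spmatrix | np.ndarray,
    genes: Sequence[str],
    cells: pd.DataFrame,
) -> pd.DataFrame:
    """Specificity for every stage, columns as a (stage, cell_type) MultiIndex.

    Genes unexpressed in a stage get specificity 0 in that stage's columns
    (rows are the union of per-stage expressed genes).
    """
    stages = list(dict.fromkeys(cells["stage"]))
    pieces = {}
    for stage in stages:
        spec = compute_specificity(counts, genes, cells, stage)
        spec.columns = pd.MultiIndex.from_product([[stage], spec.columns])
        pieces[stage] = spec
    merged = pd.concat(pieces.values(), axis=1).fillna(0.0)
    merged.columns.names = ["stage", "cell_type"]
    return merged


def ewce_bootstrap(
    targets: Iterable[str],
    specificity: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Bootstrap test of a gene set's aggregate specificity per group.

    ``observed`` is the sum of specificities of the target genes present in
    the matrix, per column group.  Each of ``n_boot`` bootstraps draws the
    same number of genes uniformly without replacement from the matrix rows;
    p = (1 + #{bootstrap sums >= observed}) / (1 + n_boot), one-sided.  When
    the bootstrap standard deviation is zero, z is NaN and p is 1.

    Returns a DataFrame with columns stage, cell_type (taken from a column
    MultiIndex, else cell_type only), observed, boot_mean, boot_sd, z, p.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    present = [g for g in dict.fromkeys(targets) if g in specificity.index]
    if not present:
        raise ValueError("no target gene present in the specificity matrix")
    values = specificity.to_numpy()
    n_genes = values.shape[0]
    k = len(present)
    observed = specificity.loc[present].to_numpy().sum(axis=0)

    # vectorized without-replacement draws: partial argsort of random keys
    keys = rng.random((n_boot, n_genes))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    select = sparse.csr_matrix(
        (
            np.ones(n_boot * k),
            (np.repeat(np.arange(n_boot), k), idx.ravel()),
        ),
        shape=(n_boot, n_genes),
    )
    boot_sums = np.asarray(select @ values)  # n_boot x groups
    boot_mean = boot_sums.mean(axis=0)
    boot_sd = boot_sums.std(axis=0, ddof=1) if n_boot > 1 else np.zeros_like(boot_mean)
    exceed = (boot_sums >= observed[None, :] - 1e-12).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_boot)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - boot_mean) / boot_sd
    z = np.where(boot_sd > 0, z, np.nan)
    p = np.where(boot_sd > 0, p, 1.0)

    if isinstance(specificity.columns, pd.MultiIndex):
        out = pd.DataFrame(
            {
                "stage": specificity.columns.get_level_values(0),
                "cell_type": specificity.columns.get_level_values(1),
            }
        )
    else:
        out = pd.DataFrame({"cell_type": list(specificity.columns)})
    out["observed"] = observed
    out["boot_mean"] = boot_mean
    out["boot_sd"] = boot_sd
    out["z"] = z
    out["p"] = p
    return out
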