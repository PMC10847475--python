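"""Gene-level collapsing burden test for ultra-rare variants.

Weighted URVs are collapsed per individual per gene to a burden score equal
to the maximum weight among carried qualified variants.  Each gene with at
least ``min_qualified`` qualified variants is tested case vs control: the
burden is dichotomized at a set of thresholds, each resulting 2x2 carrier
table is tested with a two-sided Fisher exact test, and the per-threshold
p-values are combined with the Cauchy combination (ACAT).  Supporting
statistics: Haldane-Anscombe-corrected odds ratios, label-permutation
expected p-value quantiles for QQ calibration, the genomic inflation factor
lambda_GC, and Storey-Tibshirani q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "BurdenMatrix",
    "collapse_burden",
    "eligible_genes",
    "fisher_exact_2x2",
    "cauchy_combine",
    "odds_ratio",
    "gene_burden_test",
    "permute_expected_pvalues",
    "genomic_inflation_lambda",
    "qvalues_storey",
    "DEFAULT_THRESHOLDS",
]

# Burden dichotomization thresholds: 0.0 means "burden > 0" (any qualified
# carrier); a positive t means "burden >= t".  With weights bounded by 1,
# t = 1.0 selects carriers of a full-weight (pLoF-like) variant.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.0, 0.5, 1.0)

_P_CLIP = 1e-16  # ACAT input clipping, keeps tan() finite
_P_ONE = 1.0 - 1e-9  # treat p at/above this as exactly 1 (discrete tests)
_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.45493...


@dataclass(frozen=True)
class BurdenMatrix:
    """Per-individual per-gene burden scores.

    ``scores[i, j]`` is the maximum weight among qualified URVs that sample
    ``samples[i]`` carries in gene ``genes[j]``; 0 when the sample carries
    none.  Scores therefore lie in [0, 1].
    """

    samples: np.ndarray  # (n_samples,) sample ids
    genes: np.ndarray  # (n_genes,) gene symbols
    scores: np.ndarray  # (n_samples, n_genes) float

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.samples), len(self.genes)):
            raise ValueError("scores shape does not match samples x genes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.samples, columns=self.genes)


def collapse_burden(
    variants: pd.DataFrame,
    carriers: pd.DataFrame,
    samples: Sequence[str],
    genes: Sequence[str] | None = None,
) -> BurdenMatrix:
    """Collapse weighted variants into a samples x genes max-weight matrix.

    Parameters
    ----------
    variants : DataFrame
        Must carry ``variant_id``, ``gene`` and ``weight`` columns (URV
        filtering and weighting already applied).  Zero-weight variants
        contribute nothing.
    carriers : DataFrame
        Long table (variant_id, sample_id); het and hom carriers are
        equivalent.  Carriers of variants absent from ``variants`` raise;
        carriers of unknown samples raise.
    samples : sequence
        Ordered sample universe (defines matrix rows, including
        burden-0 samples).
    genes : sequence, optional
        Ordered gene universe; defaults to the genes present in ``variants``.
    """
    samples = np.asarray(list(samples), dtype=object)
    if genes is None:
        genes = pd.unique(variants["gene"])
    genes = np.asarray(list(genes), dtype=object)
    scores = np.zeros((len(samples), len(genes)), dtype=float)
    if len(variants) and len(carriers):
        vmeta = variants.set_index("variant_id")[["gene", "weight"]]
        unknown_variant = ~carriers["variant_id"].isin(vmeta.index)
        if unknown_variant.any():
            vid = carriers.loc[unknown_variant, "variant_id"].iloc[0]
            raise KeyError(f"carrier references unknown variant {vid!r}")
        sample_pos = pd.Series(np.arange(len(samples)), index=samples)
        gene_pos = pd.Series(np.arange(len(genes)), index=genes)
        rows = carriers["sample_id"].map(sample_pos)
        if rows.isna().any():
            sid = carriers.loc[rows.isna(), "sample_id"].iloc[0]
            raise KeyError(f"carrier references unknown sample {sid!r}")
        hit_genes = carriers["variant_id"].map(vmeta["gene"])
        cols = hit_genes.map(gene_pos)
        weights = carriers["variant_id"].map(vmeta["weight"]).to_numpy(dtype=float)
        keep = cols.notna().to_numpy() & (weights > 0)
        np.maximum.at(
            scores,
            (rows.to_numpy(dtype=float)[keep].astype(int),
             cols.to_numpy(dtype=float)[keep].astype(int)),
            weights[keep],
        )
    return BurdenMatrix(samples=samples, genes=genes, scores=scores)


def eligible_genes(variants: pd.DataFrame, min_qualified: int = 10) -> list[str]:
    """Genes with at least ``min_qualified`` distinct qualified variants.

    A qualified variant has nonzero weight; the count is over distinct
    variant ids across the whole cohort.
    """
    if variants.empty:
        return []
    qualified = variants.loc[variants["weight"] != 0]
    counts = qualified.groupby("gene")["variant_id"].nunique()
    return sorted(counts.index[counts >= min_qualified])


# ---------------------------------------------------------------------------
# Fisher exact machinery
#
# The two-sided p-value of a 2x2 table is the sum of hypergeometric point
# probabilities (over tables with the same margins) not exceeding that of
# the observed table.  For the burden test the table margins are fixed per
# gene and threshold while the case-carrier count a varies across
# permutations, so p-values are precomputed as a lookup over all attainable
# a — this makes the 1000-fold label permutation cheap.
# ---------------------------------------------------------------------------

_REL_TOL = 1.0 + 1e-7  # tie tolerance for pmf comparison, as in scipy


def _fisher_lookup(m: int, r: int, n: int, mid: bool = False) -> np.ndarray:
    """Two-sided Fisher p for every attainable carrier split.

    For a 2x2 table with carrier margin ``m`` (= a + c), case margin ``r``
    (= a + b) and total ``n``, returns ``p[a]`` for a = 0..m, where ``p[a]``
    is the two-sided Fisher exact p-value of the table
    [[a, r - a], [m - a, n - r - m + a]].  Entries for impossible ``a`` are 1.

    With ``mid=True`` the mid-p variant is returned: outcomes as likely as
    the observed one contribute half their probability.  Mid-p values have
    null mean 0.5 and are the calibrated choice when many discrete p-values
    are combined; degenerate margins (m = 0 or m = n) still yield p = 1.
    """
    if n == 0 or (mid and (m == 0 or m == n)):
        return np.ones(m + 1)
    a = np.arange(m + 1)
    pmf = stats.hypergeom.pmf(a, n, m, r)
    order = np.argsort(pmf, kind="mergesort")
    sorted_pmf = pmf[order]
    cumulative = np.cumsum(sorted_pmf)
    # p[a] = total probability of outcomes with pmf <= pmf[a] (with slack
    # for floating ties)
    hi = np.searchsorted(sorted_pmf, pmf * _REL_TOL, side="right") - 1
    p = np.where(hi >= 0, cumulative[np.clip(hi, 0, m)], 0.0)
    if mid:
        lo = np.searchsorted(sorted_pmf, pmf / _REL_TOL, side="left") - 1
        p_strict = np.where(lo >= 0, cumulative[np.clip(lo, 0, m)], 0.0)
        p = 0.5 * (p + p_strict)
    p = np.clip(p, 0.0, 1.0)
    p[pmf == 0] = 1.0  # impossible splits: degenerate, contribute p = 1
    return p


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test of the table [[a, b], [c, d]].

    p is the sum of hypergeometric point probabilities (same margins) that do
    not exceed the observed table's probability; p is in (0, 1].
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    table = _fisher_lookup(a + c, a + b, n)
    return float(table[a])


def cauchy_combine(
    p_values: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Combine p-values with the Cauchy combination (ACAT).

    T = sum_i w_i * tan((0.5 - p_i) * pi); combined p = 0.5 - arctan(T / sum w) / pi.
    Inputs are clipped to [1e-16, 1 - 1e-16] to keep tan finite; the result is
    invariant to rescaling all weights by a positive constant.

    A component p of exactly 1 (common with discrete component tests) would
    otherwise dominate T and drag the combination to 1; following the
    standard Cauchy-combination implementation, when any component equals 1
    the Bonferroni-style fallback min(1, d * min(p)) is returned instead.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cauchy_combine requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match p-values")
    if np.any(p >= _P_ONE):
        return float(min(1.0, p.size * p.min()))
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    t = np.sum(w * np.tan((0.5 - p) * np.pi)) / np.sum(w)
    return float(0.5 - np.arctan(t) / np.pi)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a*d)/(b*c) of the table [[a, b], [c, d]].

    When any cell is zero the Haldane-Anscombe correction (+0.5 to every
    cell) is applied.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be nonnegative")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def _threshold_masks(scores: np.ndarray, thresholds: Sequence[float]) -> list[np.ndarray]:
    """Boolean carrier matrices, one per dichotomization threshold."""
    masks = []
    for t in thresholds:
        if t < 0 or t > 1:
            raise ValueError("thresholds must lie in [0, 1]")
        masks.append(scores > 0 if t == 0 else scores >= t)
    return masks


def _case_mask(samples: np.ndarray, labels: pd.DataFrame) -> np.ndarray:
    status = labels.set_index("sample_id")["status"]
    missing = [s for s in samples if s not in status.index]
    if missing:
        raise KeyError(f"sample {missing[0]!r} missing from label table")
    mask = status.loc[samples].eq("case").to_numpy()
    if mask.all() or not mask.any():
        raise ValueError("labels must contain at least one case and one control")
    return mask


def _pvalue_lookup_tables(
    masks: list[np.ndarray], n_cases: int, n_samples: int, mid: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flattened Fisher lookup tables for every (gene, threshold) margin.

    Returns (flat, offsets, carrier_totals): for threshold k and gene j,
    ``flat[offsets[k, j] + a]`` is the two-sided p at case-carrier count a;
    ``carrier_totals[k, j]`` = m.  Lookup tables are cached per distinct m.
    """
    n_thresh = len(masks)
    n_genes = masks[0].shape[1]
    totals = np.stack([mk.sum(axis=0) for mk in masks])  # (n_thresh, n_genes)
    cache: dict[int, np.ndarray] = {}
    offsets = np.zeros((n_thresh, n_genes), dtype=np.int64)
    chunks: list[np.ndarray] = []
    pos = 0
    for k in range(n_thresh):
        for j in range(n_genes):
            m = int(totals[k, j])
            tab = cache.get(m)
            if tab is None:
                tab = _fisher_lookup(m, n_cases, n_samples, mid=mid)
                cache[m] = tab
            offsets[k, j] = pos
            chunks.append(tab)
            pos += len(tab)
    flat = np.concatenate(chunks) if chunks else np.zeros(0)
    return flat, offsets, totals


def _combine_thresholds(per_threshold_p: np.ndarray) -> np.ndarray:
    """Equal-weight Cauchy combination along axis 0 (vectorized).

    Components with p = 1 are uninformative dichotomizations (degenerate
    margins, which keep p = 1 under every label permutation) and are dropped
    from the combination; a gene where every component is 1 gets combined
    p = 1.
    """
    informative = per_threshold_p < _P_ONE
    k = informative.sum(axis=0)
    p = np.clip(per_threshold_p, _P_CLIP, 1.0 - _P_CLIP)
    tan_terms = np.where(informative, np.tan((0.5 - p) * np.pi), 0.0)
    with np.errstate(invalid="ignore"):
        t = tan_terms.sum(axis=0) / k
    combined = 0.5 - np.arctan(t) / np.pi
    return np.where(k == 0, 1.0, combined)


def gene_burden_test(
    burden: BurdenMatrix,
    labels: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Case-control burden test of every gene in the matrix.

    For each threshold t the cohort is cross-classified as (burden >= t) x
    (case/control) and tested with the two-sided Fisher exact test; the
    per-threshold p-values are combined with the equal-weight Cauchy
    combination.  Carrier counts and the odds ratio are reported at
    burden > 0.

    Returns a DataFrame with columns gene, n_qualified_variants,
    case_carriers, control_carriers, odds_ratio, p_combined and the
    per-threshold p-values as ``p_t<threshold>`` columns.  q-values are not
    added here (see :func:`qvalues_storey`).
    """
    case = _case_mask(burden.samples, labels)
    n_cases = int(case.sum())
    n_samples = len(burden.samples)
    masks = _threshold_masks(burden.scores, thresholds)
    flat, offsets, totals = _pvalue_lookup_tables(masks, n_cases, n_samples)

    case_f = case.astype(float)
    per_p = np.empty((len(thresholds), len(burden.genes)))
    a_counts = np.empty((len(thresholds), len(burden.genes)), dtype=np.int64)
    for k, mk in enumerate(masks):
        a = case_f @ mk  # case carriers per gene
        a_counts[k] = np.round(a).astype(np.int64)
        per_p[k] = flat[offsets[k] + a_counts[k]]
    p_combined = _combine_thresholds(per_p)

    carriers_any = totals[0]
    case_carr = a_counts[0]
    ctrl_carr = carriers_any - case_carr
    ors = np.array(
        [
            odds_ratio(
                int(case_carr[j]),
                n_cases - int(case_carr[j]),
                int(ctrl_carr[j]),
                (n_samples - n_cases) - int(ctrl_carr[j]),
            )
            for j in range(len(burden.genes))
        ]
    )
    if variants is not None:
        nq = (
            variants.loc[variants["weight"] != 0]
            .groupby("gene")["variant_id"]
            .nunique()
        )
        n_qualified = pd.Series(burden.genes).map(nq).fillna(0).astype(int).to_numpy()
    else:
        n_qualified = np.full(len(burden.genes), -1)
    out = pd.DataFrame(
        {
            "gene": burden.genes,
            "n_qualified_variants": n_qualified,
            "case_carriers": case_carr,
            "control_carriers": ctrl_carr,
            "odds_ratio": ors,
            "p_combined": p_combined,
        }
    )
    for k, t in enumerate(thresholds):
        out[f"p_t{t:g}"] = per_p[k]
    return out


def permute_expected_pvalues(
    burden: BurdenMatrix,
    labels: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Expected p-value quantiles from case-control label permutations.

    Case/control labels are shuffled ``n_perm`` times (case count preserved),
    the full per-gene combined test is re-run on each shuffle, and the
    expected i-th order statistic is the mean over permutations of the i-th
    smallest p.  Deterministic given the seed.

    Returns a DataFrame (rank, expected_p) with rank 1 = smallest p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case = _case_mask(burden.samples, labels)
    n_cases = int(case.sum())
    n_samples = len(burden.samples)
    n_genes = len(burden.genes)
    masks = _threshold_masks(burden.scores, thresholds)
    flat, offsets, _ = _pvalue_lookup_tables(masks, n_cases, n_samples)

    # permutation matrix: each column a shuffled case-indicator
    perm = np.zeros((n_samples, n_perm), dtype=np.float64)
    for b in range(n_perm):
        idx = rng.choice(n_samples, size=n_cases, replace=False)
        perm[idx, b] = 1.0

    sum_sorted = np.zeros(n_genes)
    per_p = np.empty((len(masks), n_genes, n_perm))
    for k, mk in enumerate(masks):
        # case carriers per gene per permutation, via sparse carrier matrix
        carrier = sparse.csr_matrix(mk.T)  # genes x samples
        a = np.asarray(carrier @ perm)  # genes x n_perm
        a_int = np.round(a).astype(np.int64)
        per_p[k] = flat[offsets[k][:, None] + a_int]
    combined = _combine_thresholds(per_p)  # genes x n_perm
    combined.sort(axis=0)
    sum_sorted = combined.sum(axis=1)
    return pd.DataFrame(
        {"rank": np.arange(1, n_genes + 1), "expected_p": sum_sorted / n_perm}
    )


def genomic_inflation_lambda(p_values: Sequence[float]) -> float:
    """Genomic inflation factor: median chi2(1) statistic over its null median.

    p-values are transformed through the upper-tail chi-square(1) quantile;
    lambda near 1 indicates calibration, lambda > 1 inflation.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("genomic_inflation_lambda requires at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / _CHI2_1_MEDIAN)


def qvalues_storey(p_values: Sequence[float], lambda_: float = 0.5) -> np.ndarray:
    """Storey-Tibshirani q-values with a single-lambda pi0 estimate.

    pi0 = min(1, mean(p > lambda) / (1 - lambda)); a zero estimate falls back
    to pi0 = 1 (conservative; q-values then equal Benjamini-Hochberg adjusted
    p-values).  q for the i-th sorted p is min over j >= i of
    pi0 * m * p_(j) / j, so q-values are monotone along the p-ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < lambda_ < 1:
        raise ValueError("lambda_ must lie in (0, 1)")
    m = p.size
    pi0 = np.mean(p > lambda_) / (1.0 - lambda_)
    if pi0 <= 0:
        pi0 = 1.0
    pi0 = min(pi0, 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
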