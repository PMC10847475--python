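"""Hypergeometric over-representation of a hit-gene list in GMT gene sets.

The hit list (typically the nominally significant genes from the burden
test) is tested against each gene set with a one-sided upper-tail
hypergeometric test over a stated gene universe (by default the genes that
entered the burden test).  The fold enrichment is the hit rate inside the
pathway relative to the pathway's share of the universe:
fold = (k / n) / (K / N).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

__all__ = ["read_gmt", "hypergeometric_enrichment"]


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT file into (set id, description, members) records."""
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"GMT line {line_no}: expected id, description and at "
                    f"least one member"
                )
            records.append((parts[0], parts[1], parts[2:]))
    return records


def hypergeometric_enrichment(
    hits: Iterable[str],
    genesets: Sequence[tuple[str, str, Sequence[str]]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``hits`` in each gene set.

    Genes outside the universe are dropped from both the hit list and the
    sets before testing.  For each set, p = P(X >= k) with X hypergeometric
    (universe size N, set size K, hit-list size n).  No multiple-testing
    adjustment is applied; results are sorted by p.

    Returns a DataFrame with columns pathway_id, k, K, n, N, fold, p.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("gene universe is empty")
    hit_set = set(hits) & universe_set
    if not hit_set:
        raise ValueError("hit list is empty within the universe")
    n_universe = len(universe_set)
    n_hits = len(hit_set)
    rows = []
    for set_id, _desc, members in genesets:
        in_universe = set(members) & universe_set
        big_k = len(in_universe)
        k = len(in_universe & hit_set)
        if big_k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_hits))
        fold = (k / n_hits) / (big_k / n_universe)
        rows.append((set_id, k, big_k, n_hits, n_universe, fold, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["pathway_id", "k", "K", "n", "N", "fold", "p"]
    )
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
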