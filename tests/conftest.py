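"""Shared fixtures: small synthetic cohorts and variant-table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cvmburden import burden, simulate, variants


def make_variant_row(**overrides) -> dict:
    row = {
        "variant_id": "1-100-A-T",
        "chrom": "1",
        "pos": 100,
        "ref": "A",
        "alt": "T",
        "gene": "GENE1",
        "transcript": "ENST001",
        "canonical": True,
        "consequence": "missense",
        "damaging_prediction_count": 2,
        "gnomad_popmax_af": 0.0,
        "cohort_ac": 1,
    }
    row.update(overrides)
    return row


def variant_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame([make_variant_row(**r) for r in rows])


@pytest.fixture(scope="session")
def small_cohort():
    """Null cohort small enough for fast unit tests (no risk genes)."""
    config = simulate.SimulationConfig(
        n_cases=150, n_controls=750, n_genes=120, seed=101
    )
    return config, simulate.simulate_cohort(config)


@pytest.fixture(scope="session")
def tested_cohort(small_cohort):
    """The small cohort pushed through filter/weight/collapse, ready to test."""
    config, (var, carriers, labels) = small_cohort
    v = variants.select_canonical(var)
    v = variants.filter_urv(v)
    v = variants.assign_weights(v, variants.FUNCTIONAL_WEIGHTS)
    genes = burden.eligible_genes(v)
    eligible = v[v["gene"].isin(genes)]
    keep = carriers[carriers["variant_id"].isin(eligible["variant_id"])]
    matrix = burden.collapse_burden(
        eligible, keep, labels["sample_id"].tolist(), genes
    )
    return eligible, matrix, labels
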