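"""Burden-test statistics against independent oracles.

Fisher exact p-values are checked against exact integer enumeration of all
tables with the observed margins; the Cauchy combination against
arbitrary-precision evaluation of its defining formula (sympy); the genomic
inflation factor against a chi-square quantile built from the inverse error
function; Storey q-values against a hand-evaluated step-down and against
Benjamini-Hochberg in the pi0 = 1 regime.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cvmburden import burden
from cvmburden.burden import (
    BurdenMatrix,
    cauchy_combine,
    collapse_burden,
    eligible_genes,
    fisher_exact_2x2,
    gene_burden_test,
    genomic_inflation_lambda,
    odds_ratio,
    permute_expected_pvalues,
    qvalues_storey,
)

from conftest import variant_frame


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration over the margins."""
    m, r, n = a + c, a + b, a + b + c + d
    if n == 0:
        return 1.0
    denom = math.comb(n, m)
    nums = [
        math.comb(r, x) * math.comb(n - r, m - x)
        for x in range(m + 1)
    ]
    observed = nums[a]
    total = sum(num for num in nums if num <= observed)
    return float(Fraction(total, denom))


class TestFisherExact:
    def test_no_carriers_gives_one(self):
        assert fisher_exact_2x2(0, 80, 0, 89) == 1.0

    @pytest.mark.parametrize(
        "table",
        [(3, 7, 1, 9), (2, 98, 1, 199), (5, 0, 3, 12), (0, 5, 9, 2), (4, 4, 4, 4)],
    )
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact_2x2(*table) == pytest.approx(
            fisher_oracle(*table), abs=1e-12
        )

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 60, 4)
            ours = fisher_exact_2x2(a, b, c, d)
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    @given(st.tuples(*[st.integers(0, 25)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_transpose_symmetry(self, table):
        a, b, c, d = table
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_exact_2x2(a, c, b, d), abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


def cauchy_oracle(pvals, weights=None, digits=50):
    """Defining formula evaluated in arbitrary precision."""
    pvals = [sympy.Float(p, digits) for p in pvals]
    if weights is None:
        weights = [sympy.Integer(1)] * len(pvals)
    half = sympy.Rational(1, 2)
    t = sum(
        w * sympy.tan((half - p) * sympy.pi) for w, p in zip(weights, pvals)
    ) / sum(weights)
    return float(half - sympy.atan(t) / sympy.pi)


class TestCauchyCombine:
    def test_single_half_is_identity(self):
        assert cauchy_combine([0.5]) == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("x", [0.01, 0.2, 0.5, 0.77, 0.99])
    def test_equal_inputs_are_a_fixed_point(self, x):
        assert cauchy_combine([x, x, x]) == pytest.approx(x, rel=1e-10)

    @pytest.mark.parametrize(
        "pvals",
        [[0.01, 0.10, 0.50], [1e-6, 0.4], [0.2, 0.9, 0.95, 0.3],
         [1e-12, 0.3], [0.999, 0.05]],
    )
    def test_matches_arbitrary_precision_oracle(self, pvals):
        assert cauchy_combine(pvals) == pytest.approx(
            cauchy_oracle(pvals), abs=1e-12
        )

    def test_weighted_combination_against_oracle(self):
        p = [0.03, 0.4, 0.7]
        w = [1.0, 2.0, 0.5]
        assert cauchy_combine(p, w) == pytest.approx(
            cauchy_oracle(p, w), abs=1e-12
        )

    @given(
        st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=6),
        st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_weight_rescaling(self, pvals, scale):
        w = np.ones(len(pvals))
        assert cauchy_combine(pvals, w) == pytest.approx(
            cauchy_combine(pvals, w * scale), rel=1e-12
        )

    def test_component_of_one_uses_bonferroni_fallback(self):
        # matches the reference Cauchy-combination (CCT) handling of p = 1
        assert cauchy_combine([1e-4, 1.0, 0.3]) == pytest.approx(3e-4)
        assert cauchy_combine([1.0, 1.0]) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([])


class TestOddsRatio:
    def test_plain_arithmetic(self):
        assert odds_ratio(2, 98, 1, 199) == pytest.approx(2 * 199 / (98 * 1))

    def test_balanced_table_is_one(self):
        assert odds_ratio(7, 13, 7, 13) == 1.0

    def test_haldane_anscombe_correction(self):
        assert odds_ratio(5, 95, 0, 200) == pytest.approx(
            (5.5 * 200.5) / (95.5 * 0.5)
        )


class TestCollapseBurden:
    def base_inputs(self):
        var = variant_frame(
            [
                {"variant_id": "v1", "gene": "G1"},
                {"variant_id": "v2", "gene": "G1"},
                {"variant_id": "v3", "gene": "G2", "consequence": "synonymous"},
            ]
        )
        var["weight"] = [0.2, 0.9, 0.0]
        return var

    def test_max_weight_collapse(self):
        carriers = pd.DataFrame(
            {"variant_id": ["v1", "v2"], "sample_id": ["s1", "s1"]}
        )
        mat = collapse_burden(self.base_inputs(), carriers, ["s1", "s2"])
        frame = mat.to_frame()
        assert frame.loc["s1", "G1"] == 0.9
        assert frame.loc["s2", "G1"] == 0.0

    def test_zero_weight_variants_contribute_nothing(self):
        carriers = pd.DataFrame({"variant_id": ["v3"], "sample_id": ["s1"]})
        mat = collapse_burden(self.base_inputs(), carriers, ["s1"])
        assert mat.to_frame().loc["s1", "G2"] == 0.0

    def test_duplicate_carrier_rows_equal_single(self):
        het = pd.DataFrame({"variant_id": ["v2"], "sample_id": ["s1"]})
        hom = pd.DataFrame({"variant_id": ["v2", "v2"], "sample_id": ["s1", "s1"]})
        a = collapse_burden(self.base_inputs(), het, ["s1"]).scores
        b = collapse_burden(self.base_inputs(), hom, ["s1"]).scores
        assert np.array_equal(a, b)

    def test_unknown_variant_raises(self):
        carriers = pd.DataFrame({"variant_id": ["vX"], "sample_id": ["s1"]})
        with pytest.raises(KeyError, match="vX"):
            collapse_burden(self.base_inputs(), carriers, ["s1"])


class TestEligibleGenes:
    def make(self, n_qualified, n_zero):
        rows = [
            {"variant_id": f"q{i}", "gene": "G1"} for i in range(n_qualified)
        ] + [
            {"variant_id": f"z{i}", "gene": "G1", "consequence": "synonymous"}
            for i in range(n_zero)
        ]
        df = variant_frame(rows)
        df["weight"] = [1.0] * n_qualified + [0.0] * n_zero
        return df

    def test_ten_qualified_is_eligible(self):
        assert eligible_genes(self.make(10, 0)) == ["G1"]

    def test_nine_qualified_plus_zero_weight_is_not(self):
        assert eligible_genes(self.make(9, 5)) == []

    def test_empty_input(self):
        assert eligible_genes(variant_frame([]).assign(weight=[])) == []


class TestGeneBurdenTest:
    def make_matrix(self, scores, samples=None):
        scores = np.asarray(scores, dtype=float)
        samples = samples or [f"s{i}" for i in range(scores.shape[0])]
        genes = [f"G{j}" for j in range(scores.shape[1])]
        labels = pd.DataFrame(
            {
                "sample_id": samples,
                "status": ["case"] * (len(samples) // 2)
                + ["control"] * (len(samples) - len(samples) // 2),
            }
        )
        return BurdenMatrix(
            samples=np.array(samples, dtype=object),
            genes=np.array(genes, dtype=object),
            scores=scores,
        ), labels

    def test_unit_weights_collapse_to_single_component(self):
        # all burdens 0/1: every threshold gives the same 2x2 table, and the
        # equal-input Cauchy combination returns that single component
        rng = np.random.default_rng(5)
        scores = (rng.random((60, 4)) < 0.2).astype(float)
        mat, labels = self.make_matrix(scores)
        res = gene_burden_test(mat, labels)
        for _, row in res.iterrows():
            per = [row["p_t0"], row["p_t0.5"], row["p_t1"]]
            assert per[0] == per[1] == per[2]
            assert row["p_combined"] == pytest.approx(per[0], rel=1e-12)

    def test_zero_carrier_gene_gives_p_one(self):
        mat, labels = self.make_matrix(np.zeros((20, 1)))
        res = gene_burden_test(mat, labels)
        assert res["p_combined"].iloc[0] == 1.0
        assert res["case_carriers"].iloc[0] == 0

    def test_all_case_labels_rejected(self):
        mat, labels = self.make_matrix(np.zeros((10, 1)))
        labels["status"] = "case"
        with pytest.raises(ValueError):
            gene_burden_test(mat, labels)

    def test_carrier_counts_and_or_at_burden_gt_zero(self):
        scores = np.zeros((40, 1))
        scores[:4, 0] = 0.5   # 4 case carriers (first 20 samples are cases)
        scores[20:22, 0] = 1.0  # 2 control carriers
        mat, labels = self.make_matrix(scores)
        res = gene_burden_test(mat, labels)
        assert res["case_carriers"].iloc[0] == 4
        assert res["control_carriers"].iloc[0] == 2
        assert res["odds_ratio"].iloc[0] == pytest.approx(
            (4 * 18) / (16 * 2)
        )

    def test_planted_gene_is_detected(self, tested_cohort):
        eligible, matrix, labels = tested_cohort
        res = gene_burden_test(matrix, labels, variants=eligible)
        assert res["n_qualified_variants"].min() >= 10
        assert ((res["p_combined"] > 0) & (res["p_combined"] <= 1)).all()


class TestPermutation:
    def test_deterministic_given_seed(self, tested_cohort):
        _, matrix, labels = tested_cohort
        a = permute_expected_pvalues(matrix, labels, n_perm=20, seed=7)
        b = permute_expected_pvalues(matrix, labels, n_perm=20, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = permute_expected_pvalues(matrix, labels, n_perm=20, seed=8)
        assert not np.allclose(a["expected_p"], c["expected_p"])

    def test_expected_quantiles_are_sorted_probabilities(self, tested_cohort):
        _, matrix, labels = tested_cohort
        out = permute_expected_pvalues(matrix, labels, n_perm=25, seed=3)
        e = out["expected_p"].to_numpy()
        assert (np.diff(e) >= 0).all()
        assert ((e > 0) & (e <= 1)).all()
        assert len(out) == len(matrix.genes)

    def test_null_expected_matches_observed_distribution(self):
        """Exchangeability: permutation expectation equals the mean observed
        order statistics across independent null cohorts."""
        from cvmburden import simulate, variants as vmod

        def observed_sorted(seed):
            cfg = simulate.SimulationConfig(
                n_cases=100, n_controls=500, n_genes=60, seed=seed
            )
            var, carriers, labels = simulate.simulate_cohort(cfg)
            v = vmod.assign_weights(
                vmod.filter_urv(vmod.select_canonical(var)),
                vmod.FUNCTIONAL_WEIGHTS,
            )
            genes = eligible_genes(v)
            elig = v[v["gene"].isin(genes)]
            keep = carriers[carriers["variant_id"].isin(elig["variant_id"])]
            mat = collapse_burden(elig, keep, labels["sample_id"].tolist(), genes)
            return mat, labels

        mat, labels = observed_sorted(0)
        expected = permute_expected_pvalues(mat, labels, n_perm=300, seed=1)
        e = expected["expected_p"].to_numpy()
        reps = []
        for seed in range(1, 21):
            m, lab = observed_sorted(seed)
            res = gene_burden_test(m, lab)
            p = np.sort(res["p_combined"].to_numpy())
            reps.append(p[: len(e)] if len(p) >= len(e) else None)
        reps = [r for r in reps if r is not None]
        mean_obs = np.mean(reps, axis=0)
        se = np.std(reps, axis=0, ddof=1) / np.sqrt(len(reps))
        # bulk ranks agree within 4 Monte-Carlo SE (different cohorts share
        # the generating process, not the realized variant spectrum)
        bulk = slice(5, len(e) - 5)
        agree = np.abs(mean_obs[bulk] - e[bulk]) < 4 * se[bulk] + 0.02
        assert agree.mean() > 0.9


class TestGenomicInflation:
    def test_uniform_grid_approaches_one(self):
        p = np.arange(1, 10001) / 10001
        assert genomic_inflation_lambda(p) == pytest.approx(1.0, abs=0.02)

    def test_halving_p_increases_lambda(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.01, 1, 500)
        assert genomic_inflation_lambda(p / 2) > genomic_inflation_lambda(p)

    def test_against_erfinv_quantile_oracle(self):
        # chi2(1) upper quantile of p equals (sqrt(2) * erfinv(1 - p))**2
        p = [0.01, 0.5, 0.9]
        chi = [
            float((sympy.sqrt(2) * sympy.erfinv(sympy.Float(1 - x, 40))) ** 2)
            for x in p
        ]
        expected = np.median(chi) / float(
            (sympy.sqrt(2) * sympy.erfinv(sympy.Rational(1, 2))) ** 2
        )
        assert genomic_inflation_lambda(p) == pytest.approx(expected, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation_lambda([])


class TestStoreyQvalues:
    def test_hand_evaluated_step_down(self):
        p = np.array([0.01, 0.02, 0.03, 0.8, 0.9])
        q = qvalues_storey(p, lambda_=0.5)
        # pi0 = (2/5)/0.5 = 0.8; raw = [.04, .04, .04, .8, .72]; step-down
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.72, 0.72])

    def test_all_ones(self):
        assert np.array_equal(qvalues_storey(np.ones(5)), np.ones(5))

    def test_bh_equivalence_when_pi0_is_one(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(0.5, 1.0, 40)  # everything above lambda => pi0 = 1
        p[:5] = [1e-4, 2e-3, 0.01, 0.2, 0.4]
        if np.mean(p > 0.5) / 0.5 < 1:
            p = np.concatenate([p, np.full(40, 0.99)])
        q = qvalues_storey(p, lambda_=0.5)
        bh = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx(bh, rel=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=80, deadline=None)
    def test_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        q = qvalues_storey(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues_storey([0.5, 1.2])
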