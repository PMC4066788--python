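"""The 2m:1p binomial test, joint reciprocal P-values and rank FDR."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from imprintseq.imprinting import (
    aggregate_to_genes,
    binom_onesided,
    classify_loci,
    detect_accession_bias,
    fdr_rank,
    joint_p,
)
from imprintseq.simulate import simulate_locus_counts


def exact_tail(k, n, p0, direction):
    """Independent oracle: exact rational tail sum of the binomial mass."""
    p = Fraction(p0).limit_denominator(10**6)
    rng = range(k, n + 1) if direction == "greater" else range(0, k + 1)
    total = sum(
        Fraction(math.comb(n, i)) * p**i * (1 - p) ** (n - i) for i in rng
    )
    return float(total)


class TestBinomOnesided:
    @pytest.mark.parametrize(
        "k,n,p0,direction,expected",
        [
            (20, 20, 2 / 3, "greater", (2 / 3) ** 20),
            (0, 10, 2 / 3, "greater", 1.0),
            (10, 10, 1 / 3, "greater", (1 / 3) ** 10),
        ],
    )
    def test_closed_form_examples(self, k, n, p0, direction, expected):
        assert binom_onesided(k, n, p0, direction) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_for_small_n(self):
        for n in range(1, 15):
            for k in range(n + 1):
                for direction in ("greater", "less"):
                    got = binom_onesided(k, n, 2 / 3, direction)
                    assert got == pytest.approx(
                        exact_tail(k, n, 2 / 3, direction), abs=1e-12
                    )

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_inputs_rejected(self, k, n):
        with pytest.raises(ValueError):
            binom_onesided(k, n, 2 / 3)

    def test_tails_are_complementary(self):
        # P(X >= k) + P(X <= k-1) = 1
        for k in range(1, 21):
            assert binom_onesided(k, 20, 2 / 3, "greater") + binom_onesided(
                k - 1, 20, 2 / 3, "less"
            ) == pytest.approx(1.0, abs=1e-12)


class TestJointP:
    def test_arithmetic(self):
        assert joint_p(0.02, 0.01) == pytest.approx(0.0004)
        assert joint_p(1.0, 0.3) == 1.0
        assert joint_p(1.0, 0.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            joint_p(1.2, 0.5)

    def test_uniform_null_distribution(self):
        rng = np.random.default_rng(123)
        p1, p2 = rng.random(20_000), rng.random(20_000)
        joint = np.maximum(p1, p2) ** 2
        ks = stats.kstest(joint, "uniform")
        assert ks.pvalue > 0.01


class TestFdrRank:
    def test_formula_examples(self):
        assert fdr_rank([1e-4, 0.01, 0.2]) == pytest.approx([3e-4, 0.015, 0.2])
        q = 0.02
        assert sorted(fdr_rank([q, q, q])) == pytest.approx([q, 1.5 * q, 3 * q])

    def test_empty_list(self):
        assert len(fdr_rank([])) == 0

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_pass_matches_step_up_oracle(self, ps):
        got = fdr_rank(ps, monotone=True)
        # brute-force BH step-up: q_i = min_{j: p_j >= p_i} p_(j) * n / rank_j
        n = len(ps)
        order = np.argsort(np.asarray(ps), kind="stable")
        expected_sorted = [ps[order[i]] * n / (i + 1) for i in range(n)]
        for i in range(n - 2, -1, -1):
            expected_sorted[i] = min(expected_sorted[i], expected_sorted[i + 1])
        expected = np.empty(n)
        expected[order] = expected_sorted
        assert got == pytest.approx(expected)
        # and in P-sorted order the monotone FDR is non-decreasing with P
        assert np.all(np.diff(got[order]) >= -1e-12)


def _table(mat_axb, n_axb, mat_bxa, n_bxa):
    return pd.DataFrame(
        {
            "scaffold": ["s1"] * len(mat_axb),
            "pos": np.arange(len(mat_axb)),
            "mat_AxB": mat_axb,
            "pat_AxB": np.asarray(n_axb) - np.asarray(mat_axb),
            "mat_BxA": mat_bxa,
            "pat_BxA": np.asarray(n_bxa) - np.asarray(mat_bxa),
        }
    )


class TestClassifyLoci:
    def test_strong_maternal_bias_called_meg(self):
        out = classify_loci(_table([95], [100], [92], [100]))
        assert out["class"].iloc[0] == "MEG"
        assert out["joint_P_mat"].iloc[0] < 1e-8
        assert out["completeness"].iloc[0] == "partial"

    def test_null_proportion_called_biallelic(self):
        out = classify_loci(_table([67], [100], [66], [100]))
        assert out["class"].iloc[0] == "biallelic"

    def test_uniparental_filter_applies_in_both_crosses(self):
        out = classify_loci(_table([95], [100], [85], [100]))
        assert out["class"].iloc[0] == "biallelic"
        assert out["fdr_mat"].iloc[0] <= 0.05  # FDR alone would have passed

    def test_complete_imprinting_annotation(self):
        out = classify_loci(_table([50], [50], [40], [40]))
        assert out["class"].iloc[0] == "MEG"
        assert out["completeness"].iloc[0] == "complete"

    def test_peg_called_symmetrically(self):
        out = classify_loci(_table([5], [100], [8], [100]))
        assert out["class"].iloc[0] == "PEG"

    def test_parent_relabelling_swaps_meg_and_peg(self):
        rng = np.random.default_rng(5)
        n = 200
        mat_axb = rng.binomial(60, np.r_[np.full(100, 2 / 3), np.full(50, 0.97), np.full(50, 0.03)])
        mat_bxa = rng.binomial(60, np.r_[np.full(100, 2 / 3), np.full(50, 0.97), np.full(50, 0.03)])
        tab = _table(mat_axb, [60] * n, mat_bxa, [60] * n)
        out = classify_loci(tab)
        swapped = tab.rename(
            columns={
                "mat_AxB": "pat_AxB",
                "pat_AxB": "mat_AxB",
                "mat_BxA": "pat_BxA",
                "pat_BxA": "mat_BxA",
            }
        )
        out_sw = classify_loci(swapped)
        remap = {"MEG": "PEG", "PEG": "MEG", "biallelic": "biallelic"}
        assert out_sw["class"].tolist() == [remap[c] for c in out["class"]]

    def test_zero_read_loci_excluded(self):
        tab = _table([10, 0], [15, 0], [9, 0], [14, 0])
        out = classify_loci(tab)
        assert len(out) == 1

    def test_type_i_error_controlled_on_null_tables(self):
        tab = simulate_locus_counts(seed=11, n_null=5000, n_imprinted=0, coverage=30)
        out = classify_loci(tab)
        frac_called = (out["class"] != "biallelic").mean()
        assert frac_called <= 0.001


class TestAccessionBias:
    def test_line_bias_in_both_directions_called(self):
        tab = _table([95, 67], [100, 100], [7, 66], [100, 100])
        out = detect_accession_bias(tab)
        assert out["biased_line"].tolist() == ["p1", ""]

    def test_parent_of_origin_pattern_not_accession_bias(self):
        # line-A fraction 0.95 in AxB but 0.05 in BxA: imprinting, not line bias
        tab = _table([95], [100], [95], [100])
        out = detect_accession_bias(tab)
        assert out["biased_line"].iloc[0] == ""

    def test_one_cross_below_threshold_not_called(self):
        tab = _table([91], [100], [100 - 89], [100])
        out = detect_accession_bias(tab)
        assert out["biased_line"].iloc[0] == ""

    def test_disjoint_from_imprinting_calls(self):
        tab = simulate_locus_counts(seed=3, n_null=500, n_imprinted=50, coverage=50)
        out = detect_accession_bias(classify_loci(tab))
        assert ((out["class"] != "biallelic") & (out["biased_line"] != "")).sum() == 0


class TestAggregateToGenes:
    @pytest.fixture()
    def genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "scaffold": ["s1", "s1"],
                "start": [1000, 5000],
                "end": [2000, 6000],
                "strand": ["+", "-"],
            }
        )

    def _loci(self, rows):
        df = pd.DataFrame(rows, columns=["scaffold", "pos", "class"])
        for col in ("mat_AxB", "pat_AxB", "mat_BxA", "pat_BxA"):
            df[col] = 10
        return df

    def test_unanimous_loci_support_one_gene_call(self, genes):
        loci = self._loci([("s1", 1100, "MEG"), ("s1", 1500, "MEG"), ("s1", 1900, "MEG")])
        calls, intergenic = aggregate_to_genes(loci, genes)
        assert len(calls) == 1 and len(intergenic) == 0
        assert calls.iloc[0]["class"] == "MEG"
        assert calls.iloc[0].supporting_loci == 3
        assert calls.iloc[0].mat_AxB == 30

    def test_conflicting_loci_flagged_discordant(self, genes):
        loci = self._loci([("s1", 1100, "MEG"), ("s1", 1500, "PEG")])
        calls, _ = aggregate_to_genes(loci, genes)
        assert calls.iloc[0]["class"] == "discordant"

    def test_intergenic_locus_reported_with_distance_and_side(self, genes):
        # 300 bp past the end of + strand gene gA (end 2000)
        loci = self._loci([("s1", 2299, "MEG")])
        _, intergenic = aggregate_to_genes(loci, genes)
        row = intergenic.iloc[0]
        assert row["class"] == "intergenic_MEG_like"
        assert row.nearest_gene == "gA"
        assert row.distance == 300
        assert row.side == "downstream"

    def test_locus_on_unannotated_scaffold(self, genes):
        loci = self._loci([("s9", 100, "PEG")])
        _, intergenic = aggregate_to_genes(loci, genes)
        assert intergenic.iloc[0].nearest_gene == ""
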