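"""Bisulfite mapping, CpG calling, metagene profiles and DMR calling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imprintseq._seqmatch import Placement, revcomp
from imprintseq.methylation import (
    audit_dmrs,
    call_allele_dmrs,
    call_cytosines,
    call_dmrs,
    dmr_gene_overlap,
    hypomethylation_association,
    map_bisulfite_reads,
    metagene_profile,
)
from imprintseq.simulate import (
    SimConfig,
    gen_bisulfite_reads,
    make_truth,
    methylation_levels,
)


def _genome(seed=0, length=4000):
    rng = np.random.default_rng(seed)
    return {"s1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])}


class TestBisulfiteMapping:
    def test_fully_converted_read_places_cleanly(self):
        genome = _genome()
        read = genome["s1"][100:190].replace("C", "T")
        ((rid, p, oriented),) = map_bisulfite_reads([("r", read)], genome)
        assert (p.scaffold, p.start, p.strand, p.mismatches) == ("s1", 100, "+", 0)

    def test_crick_strand_read_places_cleanly(self):
        genome = _genome()
        template = revcomp(genome["s1"][100:190])
        read = template.replace("C", "T")
        ((rid, p, oriented),) = map_bisulfite_reads([("r", read)], genome)
        assert (p.scaffold, p.start, p.strand) == ("s1", 100, "-")

    def test_multi_mapping_read_dropped(self):
        seq = _genome(seed=3)["s1"][:300]
        genome = {"s1": seq, "s2": seq}
        read = seq[50:140]
        assert map_bisulfite_reads([("r", read)], genome) == []
        hits = map_bisulfite_reads([("r", read)], genome, unique_only=False)
        assert len(hits) == 1

    def test_three_true_mismatches_unplaced(self):
        genome = _genome()
        read = list(genome["s1"][100:190])
        flip = {"A": "G", "G": "C", "C": "A", "T": "A"}
        for i in (10, 40, 70):
            read[i] = flip[read[i]]
        assert map_bisulfite_reads([("r", "".join(read))], genome, max_mismatch=2) == []


class TestCallCytosines:
    def _placements(self, genome, n, mutate=None):
        seq = genome["s1"][0:90]
        if mutate:
            seq = mutate(seq)
        return [(f"r{i}", Placement("s1", 0, "+", 0), seq) for i in range(n)]

    def test_all_methylated_level_one(self):
        genome = _genome(seed=4)
        calls = call_cytosines(self._placements(genome, 10), genome)
        assert (calls.level == 1.0).all()
        assert (calls.context == "CpG").all()

    def test_mixed_counts_level(self):
        genome = _genome(seed=4)
        plc = self._placements(genome, 4) + [
            (f"t{i}", Placement("s1", 0, "+", 0), genome["s1"][0:90].replace("C", "T"))
            for i in range(6)
        ]
        calls = call_cytosines(plc, genome)
        assert (calls.c_count == 4).all()
        assert (calls.t_count == 6).all()
        assert calls.level.iloc[0] == pytest.approx(0.4)

    def test_non_ct_base_ignored(self):
        genome = _genome(seed=4)
        plc = self._placements(genome, 1, mutate=lambda s: s.replace("C", "G"))
        calls = call_cytosines(plc, genome)
        assert len(calls) == 0

    def test_caller_recovers_generator_truth(self):
        cfg = SimConfig(
            seed=21, n_scaffolds=1, scaffold_len=20_000, n_genes=4,
            coverage_bs=50, frac_meg=0.5, frac_meg_hypo=1.0, frac_meg_allele_dmr=0.0,
        )
        truth = make_truth(cfg)
        genome = truth.haplotypes["p1"]
        reads, _ = gen_bisulfite_reads(cfg, "endosperm", truth)
        calls = call_cytosines(map_bisulfite_reads(reads, genome), genome)
        levels = methylation_levels(truth, "endosperm")["scaffold_1"][0]
        # compare pooled observed level with truth region by region
        regions = [(g.start, g.end) for g in truth.genes.itertuples()]
        regions.append((0, truth.genes.start.min()))
        for start, end in regions:
            sub = calls[(calls.pos >= start) & (calls.pos < end)]
            obs = sub.c_count.sum() / (sub.c_count.sum() + sub.t_count.sum())
            expected = levels[start:end].mean()
            assert abs(obs - expected) < 0.02


class TestMetageneProfile:
    def test_uniform_methylation_gives_flat_unit_profile(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(20_000, size=2_000, replace=False))
        calls = pd.DataFrame(
            {"scaffold": "s1", "pos": pos, "strand": "+", "context": "CpG",
             "c_count": 10, "t_count": 0, "level": 1.0}
        )
        genes = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "scaffold": "s1", "start": [5000, 12_000],
             "end": [8000, 15_000], "strand": ["+", "-"]}
        )
        prof = metagene_profile(calls, genes)
        covered = prof[prof.n_features > 0]
        assert len(covered) > 0
        assert (covered.mean_level == 1.0).all()

    def test_endosperm_profile_below_embryo_profile(self):
        cfg = SimConfig(
            seed=22, n_scaffolds=1, scaffold_len=30_000, n_genes=5, coverage_bs=30,
            meth_endosperm=0.3, meth_embryo=0.8, frac_meg=0, frac_peg=0,
            frac_accession_biased=0, frac_other_hypo=0, frac_meg_allele_dmr=0,
        )
        truth = make_truth(cfg)
        genome = truth.haplotypes["p1"]
        profs = {}
        for sample in ("endosperm", "embryo"):
            reads, _ = gen_bisulfite_reads(cfg, sample, truth)
            calls = call_cytosines(map_bisulfite_reads(reads, genome), genome)
            profs[sample] = metagene_profile(calls, truth.genes)
        both = (profs["endosperm"].n_features > 0) & (profs["embryo"].n_features > 0)
        assert both.sum() > 10
        assert (
            profs["endosperm"].mean_level[both] < profs["embryo"].mean_level[both]
        ).all()

    def test_strand_reversal_mirrors_bins(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(10_000, size=1_500, replace=False))
        calls = pd.DataFrame(
            {"scaffold": "s1", "pos": pos, "strand": "+", "context": "CpG",
             "c_count": 5, "t_count": 5, "level": rng.random(1_500)}
        )
        fwd = pd.DataFrame(
            {"gene_id": ["g"], "scaffold": "s1", "start": [4000], "end": [6000], "strand": ["+"]}
        )
        rev = fwd.assign(strand="-")
        p_fwd = metagene_profile(calls, fwd, anchor="five_prime")
        p_rev = metagene_profile(calls, rev, anchor="three_prime")
        a = p_fwd.mean_level.to_numpy()
        b = p_rev.mean_level.to_numpy()[::-1]
        mask = ~np.isnan(a) & ~np.isnan(b)
        assert mask.sum() > 5
        np.testing.assert_allclose(a[mask], b[mask])


def _site_calls(positions, level, reads, scaffold="s1"):
    c = int(round(level * reads))
    return pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": positions,
            "strand": "+",
            "context": "CpG",
            "c_count": c,
            "t_count": reads - c,
            "level": c / reads,
        }
    )


class TestCallDmrs:
    def test_textbook_segment_called(self):
        pos = [100, 124, 148, 172, 196, 220]
        a = _site_calls(pos, 0.1, 20)
        b = _site_calls(pos, 0.9, 20)
        out = call_dmrs(a, b)
        assert len(out) == 1
        seg = out.iloc[0]
        assert (seg.start, seg.end, seg.n_sites) == (100, 221, 6)
        assert seg["diff"] == pytest.approx(-0.8)
        # chi-square oracle on the pooled table (12,108) vs (108,12)
        obs = np.array([[12, 108], [108, 12]])
        expect = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2 = ((obs - expect) ** 2 / expect).sum()
        assert seg.chi2_p == pytest.approx(stats.chi2.sf(chi2, 1))
        assert seg.chi2_p < 0.05

    def test_short_span_rejected(self):
        pos = [100, 107, 114, 121, 128, 135]  # span 36 bp
        out = call_dmrs(_site_calls(pos, 0.1, 20), _site_calls(pos, 0.9, 20))
        assert len(out) == 0

    def test_identical_samples_give_no_segments(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(5_000, 300, replace=False))
        a = _site_calls(pos, 0.5, 20)
        out = call_dmrs(a, a.copy())
        assert len(out) == 0

    def test_sample_swap_negates_diff(self):
        pos = [100, 124, 148, 172, 196, 220]
        a = _site_calls(pos, 0.1, 20)
        b = _site_calls(pos, 0.9, 20)
        fwd = call_dmrs(a, b)
        rev = call_dmrs(b, a)
        assert fwd[["scaffold", "start", "end", "n_sites"]].equals(
            rev[["scaffold", "start", "end", "n_sites"]]
        )
        np.testing.assert_allclose(fwd["diff"], -rev["diff"])

    def test_low_coverage_sites_excluded(self):
        pos = [100, 124, 148, 172, 196, 220]
        out = call_dmrs(_site_calls(pos, 0.1, 10), _site_calls(pos, 0.9, 10))
        assert len(out) == 0  # "more than 10 reads" is strict

    def test_gap_rule_splits_segments(self):
        pos = [100, 130, 160, 190, 220, 250, 600, 630, 660, 690, 720, 750]
        out = call_dmrs(_site_calls(pos, 0.0, 20), _site_calls(pos, 1.0, 20))
        assert len(out) == 2
        assert out.start.tolist() == [100, 600]

    def test_audit_passes_called_and_flags_corrupted(self):
        pos = [100, 124, 148, 172, 196, 220]
        a = _site_calls(pos, 0.1, 20)
        b = _site_calls(pos, 0.9, 20)
        out = call_dmrs(a, b)
        assert audit_dmrs(out, a, b) == []
        bad = out.copy()
        bad.loc[0, "length"] = 30
        assert audit_dmrs(bad, a, b)


class TestDmrGeneOverlap:
    @pytest.fixture()
    def genes(self):
        return pd.DataFrame(
            {"gene_id": ["g1"], "scaffold": ["s1"], "start": [10_000],
             "end": [12_000], "strand": ["+"]}
        )

    def _dmr(self, start, end):
        return pd.DataFrame(
            {"scaffold": ["s1"], "start": [start], "end": [end], "length": [end - start],
             "n_sites": [6], "meth_A": [0.1], "meth_B": [0.9], "diff": [-0.8],
             "chi2_p": [1e-6]}
        )

    def test_upstream_link(self, genes):
        out = dmr_gene_overlap(self._dmr(9_300, 9_500), genes)
        assert out.iloc[0].region == "upstream"

    def test_distant_dmr_not_linked(self, genes):
        out = dmr_gene_overlap(self._dmr(14_500, 14_700), genes)
        assert len(out) == 0

    def test_tss_spanning_dmr_labelled_by_midpoint(self, genes):
        out = dmr_gene_overlap(self._dmr(9_900, 10_300), genes)
        assert out.iloc[0].region == "gene_body"

    def test_minus_strand_orientation(self, genes):
        minus = genes.assign(strand="-")
        out = dmr_gene_overlap(self._dmr(9_300, 9_500), minus)
        assert out.iloc[0].region == "downstream"


class TestAlleleDmrs:
    def _calls(self, positions, level_mat, level_pat, reads=10):
        frames = []
        for parent, level in (("maternal", level_mat), ("paternal", level_pat)):
            df = _site_calls(positions, level, reads)
            df["parent"] = parent
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @pytest.fixture()
    def gene(self):
        return pd.DataFrame(
            {"gene_id": ["g1"], "scaffold": ["s1"], "start": [1_000],
             "end": [2_000], "strand": ["+"]}
        )

    def test_hypomaternal_window_qualifies(self, gene):
        pos = [1100, 1120, 1140, 1160, 1180, 1199]
        out = call_allele_dmrs(self._calls(pos, 0.33, 1.0), gene)
        assert len(out) == 1
        row = out.iloc[0]
        assert row.region == "gene_body"
        assert row.length == row.end - row.start
        assert row.meth_maternal == pytest.approx(30.0)  # 0.33 rounds to 3/10 per site
        assert row.meth_paternal == pytest.approx(100.0)
        assert row.n_informative >= 5

    def test_forty_percent_arm_enforced(self, gene):
        pos = [1100, 1120, 1140, 1160, 1180, 1199]
        out = call_allele_dmrs(self._calls(pos, 0.45, 0.8), gene)
        assert len(out) == 0

    def test_zero_vs_seventyone_qualifies(self, gene):
        pos = [1100, 1120, 1140, 1160, 1180, 1199]
        out = call_allele_dmrs(self._calls(pos, 0.0, 0.71, reads=100), gene)
        assert len(out) == 1

    def test_sparse_informative_sites_skipped(self, gene):
        out = call_allele_dmrs(self._calls([1100, 1150, 1190], 0.0, 1.0), gene)
        assert len(out) == 0

    def test_gene_relative_coordinates_on_minus_strand(self, gene):
        minus = gene.assign(strand="-")
        pos = [1100, 1120, 1140, 1160, 1180, 1199]
        out = call_allele_dmrs(self._calls(pos, 0.0, 1.0), minus)
        row = out.iloc[0]
        assert row.rel_start == minus.end.iloc[0] - row.end
        assert row.rel_end == minus.end.iloc[0] - row.start


class TestHypomethylationAssociation:
    def _enumerate_fisher(self, table):
        (a, b), (c, d) = table
        n = a + b + c + d
        r1, c1 = a + b, a + c
        probs = {
            x: math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
            for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
        }
        p_obs = probs[a]
        return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))

    def test_matches_enumeration(self):
        imp = {f"i{k}" for k in range(209)}
        hypo = {f"i{k}" for k in range(20)} | {f"b{k}" for k in range(100)}
        universe = imp | {f"b{k}" for k in range(9900)}
        p, table = hypomethylation_association(imp, universe, hypo)
        assert table == [[20, 189], [100, 9800]]
        assert p == pytest.approx(self._enumerate_fisher(table), rel=1e-9)
        assert p < 1e-4

    def test_independent_sets_not_significant(self):
        imp = {f"g{k}" for k in range(0, 100)}
        hypo = {f"g{k}" for k in range(0, 1000, 10)}  # 10% everywhere
        universe = {f"g{k}" for k in range(1000)}
        p, _ = hypomethylation_association(imp, universe, hypo)
        assert p > 0.5

    def test_degenerate_margin_gives_p_one(self):
        universe = {f"g{k}" for k in range(50)}
        p, _ = hypomethylation_association(set(), universe, {"g1"})
        assert p == 1.0
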