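import numpy as np
import pandas as pd
import pytest

from cutsurvey.architecture import (
    annotate_nfrs,
    classify_pairs,
    compare_groups,
    divergent_gene_gene_pairs,
    enrichment_4x_in_nfr,
    nfr_origin_flags,
    summarize_expression,
)
from cutsurvey.coverage import CoverageTrack
from cutsurvey.genomic_io import Annotation, Genome


def ann(start, end, strand="+", name="x", chrom="chrI"):
    return Annotation(chrom, start, end, strand, name)


class TestAnnotateNfrs:
    def test_plus_strand_windows(self):
        nfrs = {n.kind: n.interval for n in annotate_nfrs([ann(1000, 5000, "+")])}
        assert (nfrs["NFR5"].start, nfrs["NFR5"].end) == (800, 1000)
        assert (nfrs["NFR3"].start, nfrs["NFR3"].end) == (4900, 5100)

    def test_minus_strand_mirrored(self):
        nfrs = {n.kind: n.interval for n in annotate_nfrs([ann(200, 1000, "-")])}
        assert (nfrs["NFR5"].start, nfrs["NFR5"].end) == (1000, 1200)
        assert (nfrs["NFR3"].start, nfrs["NFR3"].end) == (100, 300)

    def test_fixed_window_lengths_except_at_edges(self):
        g = Genome({"chrI": 5050})
        nfrs = annotate_nfrs([ann(1000, 5000, "+")], genome=g)
        by_kind = {n.kind: n for n in nfrs}
        assert by_kind["NFR5"].interval.length == 200
        assert by_kind["NFR3"].interval.length == 150 and by_kind["NFR3"].clipped

    def test_chromosome_start_clipping(self):
        nfrs = annotate_nfrs([ann(100, 800, "+")], kinds=("NFR5",))
        assert nfrs[0].interval.start == 0 and nfrs[0].clipped


def _nfr5(feature):
    return annotate_nfrs([feature], kinds=("NFR5",))


class TestClassifyPairs:
    def _gene(self, start=2000, end=4000, strand="+"):
        return ann(start, end, strand, "gene1")

    def test_antisense_pair_at_threshold(self):
        gene = self._gene()
        # minus-strand CUT ending at the gene 3' end: its 5' NFR covers
        # [cut_end, cut_end+200), overlapping the gene NFR3 [3900,4100) by 100
        cut = ann(3000, 4000, "-", "cutA")
        pairs = classify_pairs(_nfr5(cut), annotate_nfrs([gene]))
        assert [p.configuration for p in pairs] == ["antisense"]
        assert pairs[0].overlap_bp == 100

    def test_99_bp_overlap_is_no_pair(self):
        gene = self._gene()
        cut = ann(3000, 4001, "-", "cutA")  # NFR5 [4001,4201) x NFR3 [3900,4100) = 99
        pairs = classify_pairs(_nfr5(cut), annotate_nfrs([gene]))
        assert pairs == []

    def test_divergent_pair(self):
        gene = self._gene()
        # head-to-head CUT ending 150 bp upstream of the gene TSS: shared
        # NFR5 overlap = 150 >= max(100, 50% of 200)
        cut = ann(1450, 1850, "-", "cutD")
        pairs = classify_pairs(_nfr5(cut), annotate_nfrs([gene]))
        assert [p.configuration for p in pairs] == ["divergent"]

    def test_same_sense_reported_separately(self):
        gene = self._gene()
        # same strand, NFR5 sharing the gene NFR5, body overlapping the gene
        cut = ann(1900, 2600, "+", "cutS")
        pairs = classify_pairs(_nfr5(cut), annotate_nfrs([gene]))
        assert [p.configuration for p in pairs] == ["same_sense"]

    def test_deterministic_and_input_order_independent(self):
        genes = [self._gene(), self._gene(8000, 9500)]
        cuts = [ann(3100, 4050, "-", "c1"), ann(7450, 7850, "-", "c2")]
        p1 = classify_pairs(_nfr5(cuts[0]) + _nfr5(cuts[1]), annotate_nfrs(genes))
        p2 = classify_pairs(_nfr5(cuts[1]) + _nfr5(cuts[0]), annotate_nfrs(genes[::-1]))
        key = lambda p: (p.gene.name, p.cut.name, p.configuration)
        assert sorted(map(key, p1)) == sorted(map(key, p2))


class TestDivergentGeneGene:
    def test_head_to_head_sharing(self):
        a = ann(2000, 4000, "-", "gA")
        b = ann(4150, 6000, "+", "gB")  # NFR5s [4000,4200) and [3950,4150): 150 bp shared
        pairs = divergent_gene_gene_pairs([a, b])
        assert len(pairs) == 1 and pairs[0].configuration == "divergent"

    def test_tandem_genes_no_pair(self):
        a = ann(2000, 4000, "+", "gA")
        b = ann(4150, 6000, "+", "gB")
        assert divergent_gene_gene_pairs([a, b]) == []

    def test_no_self_pairing(self):
        a = ann(2000, 4000, "+", "gA")
        assert divergent_gene_gene_pairs([a, a.with_(name="gA")]) == []


def _flat_track(genome, spans, value, strand="+"):
    t = CoverageTrack.zeros(genome)
    t.normalized = True
    for a, b in spans:
        t.data[("chrI", strand)][a:b] = value
    return t


class TestSummarizeExpression:
    def setup_method(self):
        self.genome = Genome({"chrI": 10_000})
        self.gene = ann(1000, 2000, "+", "g1")

    def test_log2_with_laplace_prior(self):
        wt = _flat_track(self.genome, [(1000, 2000)], 2.0)
        rr = _flat_track(self.genome, [(1000, 2000)], 4.0)
        df = summarize_expression([self.gene], {"WT": wt, "rrp6": rr})
        assert df.loc["g1", "log2_fc"] == pytest.approx(np.log2(5 / 3))

    def test_same_sense_cut_over_half_cds_excludes_gene(self):
        wt = _flat_track(self.genome, [(1000, 2000)], 2.0)
        cut_same = ann(1000, 2000, "+", "c")
        df = summarize_expression([self.gene], {"WT": wt}, exclusion_cuts=[cut_same])
        assert df.empty
        cut_anti = ann(1000, 2000, "-", "c")
        df = summarize_expression([self.gene], {"WT": wt}, exclusion_cuts=[cut_anti])
        assert "g1" in df.index

    def test_zero_coverage_gene_not_expressed(self):
        wt = _flat_track(self.genome, [], 0.0)
        df = summarize_expression([self.gene], {"WT": wt})
        assert not df.loc["g1", "expressed"]

    def test_repression_is_nascent_minus_wt(self):
        wt = _flat_track(self.genome, [(1000, 2000)], 2.0)
        na = _flat_track(self.genome, [(1000, 2000)], 5.0)
        df = summarize_expression([self.gene], {"WT": wt, "nascent": na})
        assert df.loc["g1", "repression"] == pytest.approx(3.0)


def _summary_frame(rng, n_bg=300, n_grp=100, shift=0.0):
    wt_bg = rng.lognormal(np.log(40), 0.7, n_bg)
    wt_grp = rng.lognormal(np.log(40) + shift * np.log(2), 0.7, n_grp)
    names = [f"bg{i}" for i in range(n_bg)] + [f"grp{i}" for i in range(n_grp)]
    wt = np.concatenate([wt_bg, wt_grp])
    df = pd.DataFrame(
        {"WT": wt, "rrp6": wt, "log2_fc": np.zeros_like(wt), "expressed": True},
        index=names,
    )
    return df, [f"grp{i}" for i in range(n_grp)]


class TestCompareGroups:
    def test_group_equal_to_background_is_ns(self):
        rng = np.random.default_rng(0)
        df, grp = _summary_frame(rng, shift=0.0)
        out = compare_groups(df.iloc[:300], {"bg": [f"bg{i}" for i in range(300)]},
                             metrics=("WT",))
        assert out.iloc[0]["D"] == 0 and out.iloc[0]["p"] == 1.0 and out.iloc[0]["ns"]

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        df, grp = _summary_frame(rng, shift=1.0)
        out = compare_groups(df, {"div": grp}, metrics=("WT",))
        assert out.iloc[0]["p"] < 0.01

    def test_small_group_rejected(self):
        rng = np.random.default_rng(2)
        df, _ = _summary_frame(rng)
        with pytest.raises(ValueError):
            compare_groups(df, {"tiny": ["bg0"]}, metrics=("WT",))

    def test_power_over_seeds(self):
        # with a +1 log2 shift at n=100 the KS comparison detects the shift
        # in essentially every replicate world
        hits = 0
        for seed in range(20):
            df, grp = _summary_frame(np.random.default_rng(seed), shift=1.0)
            out = compare_groups(df, {"div": grp}, metrics=("WT",))
            hits += out.iloc[0]["p"] < 0.05
        assert hits >= 19


class TestEnrichment:
    def test_toy_enumeration(self):
        cuts = [ann(i * 100, i * 100 + 50, name=f"c{i}") for i in range(20)]
        nfr = {f"c{i}": i < 10 for i in range(20)}          # 10 NFR-origin
        conserved = {f"c{i}": i < 8 for i in range(20)}     # 8 conserved, all NFR
        p = enrichment_4x_in_nfr(cuts, nfr, conserved)
        # P[X >= 8], X ~ Hypergeom(20, 10, 8)
        import math

        exact = sum(
            math.comb(10, j) * math.comb(10, 8 - j) for j in range(8, 9)
        ) / math.comb(20, 8)
        assert p == pytest.approx(exact)

    def test_no_conserved_cuts_gives_p_one(self):
        cuts = [ann(0, 50, name="c0"), ann(100, 150, name="c1")]
        p = enrichment_4x_in_nfr(cuts, {"c0": True}, {})
        assert p == 1.0

    def test_independent_flags_give_moderate_p(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(40):
            cuts = [ann(i * 10, i * 10 + 5, name=f"c{i}") for i in range(40)]
            nfr = {c.name: bool(rng.random() < 0.5) for c in cuts}
            cons = {c.name: bool(rng.random() < 0.5) for c in cuts}
            ps.append(enrichment_4x_in_nfr(cuts, nfr, cons))
        assert 0.2 < np.median(ps) < 0.95


class TestNfrOriginFlags:
    def test_flags_match_pair_classification(self):
        gene = ann(2000, 4000, "+", "g1")
        cut_near = ann(3000, 4000, "-", "near")   # shares the gene NFR3
        cut_far = ann(8000, 8400, "-", "far")
        flags = nfr_origin_flags([cut_near, cut_far], [gene])
        assert flags == {"near": True, "far": False}
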