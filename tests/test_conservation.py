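import numpy as np
import pytest

from cutsurvey.conservation import (
    build_map,
    classify_cuts,
    conservation_call,
    percent_identity,
    project,
    promoter_window,
    randomized_conservation,
    unique_cuts,
)
from cutsurvey.genomic_io import Annotation, Genome, MafBlock, MafSeq

STRAINS = ["A", "B", "C", "D"]


def block(texts, starts=None, chrom="chr1", src_size=200, offset_names=STRAINS):
    seqs = []
    for i, (strain, text) in enumerate(texts.items()):
        start = (starts or {}).get(strain, 0)
        seqs.append(
            MafSeq(strain, chrom, start, len(text) - text.count("-"), "+",
                   src_size, text)
        )
    return MafBlock(seqs=seqs)


def simple_map(texts, **kw):
    return build_map([block(texts, **kw)], STRAINS)


class TestBuildMap:
    def test_gapless_block_is_offset_identity(self):
        amap = simple_map({s: "ACGTACGTAC" for s in STRAINS})
        for s in STRAINS:
            assert np.array_equal(amap.col_pos[s], np.arange(10))
            assert np.array_equal(amap.pos2col[s]["chr1"][:10], np.arange(10))

    def test_gap_column_skipped_and_round_trip(self):
        amap = simple_map({"A": "AC-TACGTAC", "B": "ACGTACGTAC",
                           "C": "ACGTACGTAC", "D": "ACGTACGTAC"})
        assert amap.col_pos["A"][2] == -1
        # round-trip position -> column -> position for aligned bases
        p2c = amap.pos2col["A"]["chr1"]
        aligned = np.flatnonzero(p2c >= 0)
        assert np.array_equal(amap.col_pos["A"][p2c[aligned]], aligned)

    def test_unaligned_positions_marked(self):
        amap = simple_map({s: "ACGTA" for s in STRAINS}, src_size=50)
        assert amap.pos2col["A"]["chr1"][10] == -1

    def test_overlapping_blocks_rejected(self):
        blocks = [block({s: "ACGTA" for s in STRAINS}),
                  block({s: "CGTAC" for s in STRAINS}, starts={s: 0 for s in STRAINS})]
        with pytest.raises(ValueError, match="overlapping"):
            build_map(blocks, STRAINS)


class TestProject:
    def test_gap_free_cut_is_kept(self):
        amap = simple_map({s: "ACGTACGTAC" for s in STRAINS})
        kept, excluded = project([Annotation("chr1", 2, 8, "+", "c")], amap, "A")
        assert len(kept) == 1 and kept[0].gap_fraction == 0.0
        assert kept[0].col_start == 2 and kept[0].col_end == 8

    def test_other_strain_gaps_count_against_the_cut(self):
        # strain B gapped over 3 of A's 8 aligned nucleotides -> 37.5% > 25%
        amap = simple_map({"A": "ACGTACGTAC", "B": "AC---CGTAC",
                           "C": "ACGTACGTAC", "D": "ACGTACGTAC"})
        kept, excluded = project([Annotation("chr1", 0, 8, "+", "c")], amap, "A")
        assert not kept and excluded[0].gap_fraction == pytest.approx(3 / 8)

    def test_cut_outside_all_blocks_excluded(self):
        amap = simple_map({s: "ACGTA" for s in STRAINS}, src_size=100)
        kept, excluded = project([Annotation("chr1", 50, 60, "+", "c")], amap, "A")
        assert not kept and excluded[0].gap_fraction == 1.0

    def test_unknown_strain_rejected(self):
        amap = simple_map({s: "ACGTA" for s in STRAINS})
        with pytest.raises(ValueError):
            project([], amap, "Z")


def _projected(amap, strain, spans, strand="+"):
    anns = [Annotation("chr1", a, b, strand, f"{strain}_{a}") for a, b in spans]
    kept, _ = project(anns, amap, strain, max_gap_fraction=1.0)
    return kept


class TestConservationCall:
    def setup_method(self):
        self.amap = simple_map({s: "ACGTACGTACACGTACGTAC" for s in STRAINS})

    def test_identical_in_four_strains_is_4x(self):
        projected = {s: _projected(self.amap, s, [(2, 12)]) for s in STRAINS}
        (region,) = conservation_call(projected)
        assert region.cls == "4x" and region.mean_signal == pytest.approx(4.0)

    def test_three_strains_plus_raw_rescue(self):
        projected = {s: _projected(self.amap, s, [(2, 12)]) for s in STRAINS[:3]}
        projected["D"] = []
        rescue = {"D": _projected(self.amap, "D", [(4, 9)])}
        (region,) = conservation_call(projected, rescue)
        assert region.cls == "4x" and region.rescued

    def test_single_strain_is_unique_class(self):
        projected = {s: [] for s in STRAINS}
        projected["A"] = _projected(self.amap, "A", [(2, 12)])
        (region,) = conservation_call(projected)
        assert region.cls == "unique"

    def test_strain_order_permutation_invariant(self):
        spans = {"A": [(0, 10)], "B": [(2, 12)], "C": [(1, 9)], "D": []}
        p1 = {s: _projected(self.amap, s, spans[s]) for s in STRAINS}
        p2 = {s: _projected(self.amap, s, spans[s]) for s in reversed(STRAINS)}
        r1 = conservation_call(p1)
        r2 = conservation_call(p2)
        assert [(r.col_start, r.col_end, r.cls) for r in r1] == [
            (r.col_start, r.col_end, r.cls) for r in r2
        ]

    def test_strands_separate(self):
        projected = {s: [] for s in STRAINS}
        projected["A"] = _projected(self.amap, "A", [(2, 12)], "+")
        projected["B"] = _projected(self.amap, "B", [(2, 12)], "-")
        regions = conservation_call(projected)
        assert len(regions) == 2 and all(r.cls == "unique" for r in regions)

    def test_classify_cuts_assigns_best_region_class(self):
        projected = {s: _projected(self.amap, s, [(2, 12)]) for s in STRAINS}
        regions = conservation_call(projected)
        classes = classify_cuts(regions, projected)
        assert classes[("A", "A_2")] == "4x"


class TestUniqueCuts:
    def setup_method(self):
        self.amap = simple_map({s: "ACGTACGTACACGTACGTAC" for s in STRAINS})

    def test_raw_removed_elsewhere_blocks_uniqueness(self):
        projected = {s: [] for s in STRAINS}
        projected["A"] = _projected(self.amap, "A", [(2, 12)])
        removed = {"B": _projected(self.amap, "B", [(5, 10)])}
        out = unique_cuts(projected, removed)
        assert out["A"] == []

    def test_isolated_cut_is_unique(self):
        projected = {s: [] for s in STRAINS}
        projected["A"] = _projected(self.amap, "A", [(2, 12)])
        out = unique_cuts(projected, {})
        assert [a.name for a in out["A"]] == ["A_2"]

    def test_shared_cut_never_unique(self):
        projected = {s: _projected(self.amap, s, [(2, 12)]) for s in STRAINS}
        out = unique_cuts(projected, {})
        assert all(not v for v in out.values())


class TestPercentIdentity:
    def test_identical_sequences(self):
        amap = simple_map({s: "ACGTACGTAC" for s in STRAINS})
        assert percent_identity(amap, np.arange(10)) == 100.0

    def test_one_mismatch_of_ten_two_strains(self):
        amap = build_map(
            [block({"A": "ACGTACGTAC", "B": "ACGTACGTAT"})], ["A", "B"]
        )
        assert percent_identity(amap, np.arange(10), ["A", "B"]) == pytest.approx(90.0)

    def test_four_strains_half_divergent_hand_enumerated(self):
        # strain D differs at 5 of 10 columns; the other three agree.
        # per matching column all 6 pairs identical; per divergent column
        # only the 3 pairs within {A,B,C} are identical -> (5*6 + 5*3) / 60
        amap = simple_map({"A": "ACGTACGTAC", "B": "ACGTACGTAC",
                           "C": "ACGTACGTAC", "D": "TGCATCGTAC"})
        expected = 100 * (5 * 6 + 5 * 3) / 60
        assert percent_identity(amap, np.arange(10)) == pytest.approx(expected)

    def test_region_without_comparable_columns_rejected(self):
        amap = simple_map({s: "ACGTA" for s in STRAINS}, src_size=100)
        with pytest.raises(ValueError):
            percent_identity(amap, np.array([], dtype=int))

    def test_promoter_windows_strand_aware(self):
        cut_plus = Annotation("chr1", 500, 900, "+", "c")
        w = promoter_window(cut_plus, 300)
        assert (w.start, w.end) == (200, 500)
        cut_minus = Annotation("chr1", 500, 900, "-", "c")
        w = promoter_window(cut_minus, 50)
        assert (w.start, w.end) == (900, 950)


class TestRandomizedConservation:
    def test_fixed_seed_reproducible_and_sparse_null_is_zero(self, world, world_conservation):
        _, _, amap = world_conservation
        genomes = world.genomes
        lengths = {s: [400] * 10 for s in world.config.strains}
        c1 = randomized_conservation(genomes, lengths, amap, iterations=20, seed=3)
        c2 = randomized_conservation(genomes, lengths, amap, iterations=20, seed=3)
        assert np.array_equal(c1, c2)
        assert np.median(c1) == 0

    def test_saturating_annotations_force_top_class(self):
        amap = simple_map({s: "ACGTACGTACACGTACGTAC" for s in STRAINS},
                          src_size=20)
        genomes = {s: Genome({"chr1": 20}) for s in STRAINS}
        # enough placements that every strain covers both strands
        lengths = {s: [20] * 10 for s in STRAINS}
        counts = randomized_conservation(genomes, lengths, amap, iterations=5, seed=0)
        assert (counts >= 1).all()
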