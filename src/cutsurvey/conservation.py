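"""Conserved syntenic CUT expression via a whole-genome multiple alignment.

The multiple alignment (MAF, e.g. a Pecan product) defines a universal
column coordinate system.  Per-strain CUTs are projected into columns,
poorly aligned CUTs (indels/unaligned over more than 25% of their length)
are excluded, a per-column histogram counts strains with CUT expression,
and maximal runs of histogram >= 1 become conservation regions classified
by their mean strain count (4x / 3x / 2x / unique).  A 3-strain region is
rescued to 4x when the missing strain shows a raw-but-filtered HMM segment
at the syntenic location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import Annotation, Genome, MafBlock


@dataclass
class AlignmentMap:
    """Bidirectional strain position <-> global alignment column mapping.

    Columns are globally ordered by concatenating MAF blocks in file order.
    ``col_pos[strain][col]`` is the forward-strand position (-1 for gap or
    absent); ``pos2col[strain][chrom][pos]`` is the column (-1 unaligned).
    """

    strains: list[str]
    n_cols: int
    col_pos: dict[str, np.ndarray]
    col_chrom: dict[str, np.ndarray]          # index into chroms[strain], -1 absent
    col_base: dict[str, np.ndarray]           # uint8 base codes, 0 = gap/absent
    col_strand: dict[str, np.ndarray]         # +1 / -1 / 0 absent
    chroms: dict[str, list[str]]
    chrom_sizes: dict[str, dict[str, int]]
    pos2col: dict[str, dict[str, np.ndarray]]

    def has_base(self, strain: str) -> np.ndarray:
        return self.col_base[strain] > 0

    def columns_of(self, strain: str, ann: Annotation) -> np.ndarray:
        """Alignment columns of the aligned nucleotides of an interval."""
        cols = self.pos2col[strain][ann.chrom][ann.start : ann.end]
        return cols[cols >= 0]


def build_map(maf_blocks: Sequence[MafBlock], strains: Sequence[str]) -> AlignmentMap:
    """Index a MAF into an :class:`AlignmentMap`.  Errors on blocks that
    cover a strain position twice."""
    strains = list(strains)
    n_cols = sum(b.ncols for b in maf_blocks)
    col_pos = {s: np.full(n_cols, -1, dtype=np.int64) for s in strains}
    col_chrom = {s: np.full(n_cols, -1, dtype=np.int32) for s in strains}
    col_base = {s: np.zeros(n_cols, dtype=np.uint8) for s in strains}
    col_strand = {s: np.zeros(n_cols, dtype=np.int8) for s in strains}
    chroms: dict[str, list[str]] = {s: [] for s in strains}
    chrom_sizes: dict[str, dict[str, int]] = {s: {} for s in strains}
    offset = 0
    for blk in maf_blocks:
        for row in blk.seqs:
            if row.strain not in strains:
                continue
            s = row.strain
            if row.chrom not in chrom_sizes[s]:
                chrom_sizes[s][row.chrom] = row.src_size
                chroms[s].append(row.chrom)
            ci = chroms[s].index(row.chrom)
            text = np.frombuffer(row.text.upper().encode(), dtype=np.uint8)
            not_gap = text != ord("-")
            idx = np.flatnonzero(not_gap)
            offsets_in_row = np.cumsum(not_gap) - 1
            if row.strand == "+":
                pos = row.start + offsets_in_row[idx]
            else:
                pos = row.src_size - 1 - (row.start + offsets_in_row[idx])
            cols = offset + idx
            col_pos[s][cols] = pos
            col_chrom[s][cols] = ci
            col_base[s][cols] = text[idx]
            col_strand[s][cols] = 1 if row.strand == "+" else -1
        offset += blk.ncols
    pos2col: dict[str, dict[str, np.ndarray]] = {}
    for s in strains:
        pos2col[s] = {
            c: np.full(chrom_sizes[s][c], -1, dtype=np.int64) for c in chroms[s]
        }
        for ci, c in enumerate(chroms[s]):
            mask = col_chrom[s] == ci
            cols = np.flatnonzero(mask)
            positions = col_pos[s][cols]
            if np.unique(positions).size < positions.size:
                raise ValueError(f"overlapping MAF blocks for {s}.{c}")
            pos2col[s][c][positions] = cols
    return AlignmentMap(
        strains, n_cols, col_pos, col_chrom, col_base, col_strand,
        chroms, chrom_sizes, pos2col,
    )


@dataclass
class ProjectedCut:
    source: Annotation
    strain: str
    columns: np.ndarray          # aligned columns, ascending
    gap_fraction: float

    @property
    def col_start(self) -> int:
        return int(self.columns[0]) if self.columns.size else -1

    @property
    def col_end(self) -> int:
        return int(self.columns[-1]) + 1 if self.columns.size else -1


def project(
    cuts: Sequence[Annotation],
    amap: AlignmentMap,
    strain: str,
    max_gap_fraction: float = 0.25,
    count_other_strain_gaps: bool = True,
) -> tuple[list[ProjectedCut], list[ProjectedCut]]:
    """Project a strain's CUTs into alignment columns.

    gap_fraction = (unaligned nucleotides + nucleotides in columns gapped in
    >= 1 other strain) / CUT length; CUTs above ``max_gap_fraction`` go to
    the excluded list.
    """
    if strain not in amap.strains:
        raise ValueError(f"unknown strain {strain!r}")
    others = [s for s in amap.strains if s != strain]
    other_has_base = (
        np.all([amap.has_base(s) for s in others], axis=0) if others else
        np.ones(amap.n_cols, dtype=bool)
    )
    kept, excluded = [], []
    for cut in cuts:
        p2c = amap.pos2col[strain].get(cut.chrom)
        if p2c is None:
            cols = np.zeros(0, dtype=np.int64)
        else:
            cols = p2c[cut.start : cut.end]
            cols = np.sort(cols[cols >= 0])
        n_unaligned = cut.length - cols.size
        n_other_gapped = int((~other_has_base[cols]).sum()) if (
            count_other_strain_gaps and cols.size
        ) else 0
        gap_fraction = (n_unaligned + n_other_gapped) / cut.length
        pc = ProjectedCut(cut, strain, cols, gap_fraction)
        (kept if gap_fraction <= max_gap_fraction else excluded).append(pc)
    return kept, excluded


@dataclass
class ConservationRegion:
    strand: str
    col_start: int
    col_end: int
    mean_signal: float
    median_signal: float
    members: dict[str, list[str]]        # strain -> CUT names overlapping
    cls: str                             # "4x" / "3x" / "2x" / "unique"
    rescued: bool = False
    incongruent: bool = False

    @property
    def n_member_strains(self) -> int:
        return sum(1 for v in self.members.values() if v)


def _class_label(k: int, n_strains: int) -> str:
    k = int(np.clip(k, 1, n_strains))
    return "unique" if k == 1 else f"{k}x"


def conservation_call(
    projected_by_strain: Mapping[str, Sequence[ProjectedCut]],
    rescue_raw_by_strain: Mapping[str, Sequence[ProjectedCut]] | None = None,
    fourx_threshold: float = 3.5,
    with_members: bool = True,
) -> list[ConservationRegion]:
    """Histogram strain counts along alignment columns and classify maximal
    histogram >= 1 runs; strands handled separately.

    Classification uses the median column strain count of the region (the
    consensus strain count): top class iff median >= fourx_threshold,
    otherwise the nearest integer to the median.  The median is robust to
    the low-count flanks that per-strain boundary scatter necessarily adds
    to a maximal h >= 1 run, which pull the plain mean below the strain
    count; the mean is still reported as ``mean_signal``.  Regions with
    exactly (n_strains - 1) member strains are upgraded to the top class
    when the missing strain has a raw-but-filtered segment overlapping the
    region.  A strain's CUT spanning several regions flags them incongruent.
    """
    strains = list(projected_by_strain)
    n_strains = len(strains)
    if n_strains == 0:
        return []
    n_cols = 0
    for pcs in projected_by_strain.values():
        for pc in pcs:
            if pc.columns.size:
                n_cols = max(n_cols, pc.col_end)
    regions: list[ConservationRegion] = []
    for strand in ("+", "-"):
        cover = np.zeros((n_strains, n_cols), dtype=bool)
        for si, s in enumerate(strains):
            for pc in projected_by_strain[s]:
                if pc.source.strand == strand and pc.columns.size:
                    cover[si, pc.columns] = True
        h = cover.sum(axis=0)
        nz = h > 0
        if not nz.any():
            continue
        d = np.diff(nz.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if nz[0]:
            starts = np.concatenate(([0], starts))
        if nz[-1]:
            ends = np.concatenate((ends, [nz.size]))
        strand_regions = []
        for cs, ce in zip(starts, ends):
            mean_signal = float(h[cs:ce].mean())
            median_signal = float(np.median(h[cs:ce]))
            members = {s: [] for s in strains}
            if with_members:
                for si, s in enumerate(strains):
                    for pc in projected_by_strain[s]:
                        if (
                            pc.source.strand == strand
                            and pc.columns.size
                            and pc.col_start < ce
                            and pc.col_end > cs
                        ):
                            members[s].append(pc.source.name)
            if median_signal >= fourx_threshold:
                cls = _class_label(n_strains, n_strains)
            else:
                cls = _class_label(int(round(median_signal)), n_strains)
            region = ConservationRegion(
                strand, int(cs), int(ce), mean_signal, median_signal, members, cls
            )
            # rescue: one strain missing, but it has a raw (filtered-out) segment here
            if (
                with_members
                and rescue_raw_by_strain is not None
                and region.n_member_strains == n_strains - 1
            ):
                missing = [s for s in strains if not members[s]]
                for s in missing:
                    for pc in rescue_raw_by_strain.get(s, []):
                        if (
                            pc.source.strand == strand
                            and pc.columns.size
                            and pc.col_start < ce
                            and pc.col_end > cs
                        ):
                            region.cls = _class_label(n_strains, n_strains)
                            region.rescued = True
                            region.members[s].append(pc.source.name + "|rescued")
                            break
            strand_regions.append(region)
        # incongruence: a CUT overlapping more than one region on its strand
        for si, s in enumerate(strains) if with_members else ():
            for pc in projected_by_strain[s]:
                if pc.source.strand != strand or not pc.columns.size:
                    continue
                hits = [
                    r for r in strand_regions
                    if pc.col_start < r.col_end and pc.col_end > r.col_start
                ]
                if len(hits) > 1:
                    for r in hits:
                        r.incongruent = True
        regions.extend(strand_regions)
    return sorted(regions, key=lambda r: (r.col_start, r.col_end, r.strand))


def classify_cuts(
    regions: Sequence[ConservationRegion],
    projected_by_strain: Mapping[str, Sequence[ProjectedCut]],
) -> dict[tuple[str, str], str]:
    """Map each projected CUT (strain, name) to the best class among the
    regions it overlaps."""
    rank = {"unique": 1, "2x": 2, "3x": 3, "4x": 4}
    out: dict[tuple[str, str], str] = {}
    for strain, pcs in projected_by_strain.items():
        for pc in pcs:
            best = None
            for r in regions:
                if (
                    r.strand == pc.source.strand
                    and pc.columns.size
                    and pc.col_start < r.col_end
                    and pc.col_end > r.col_start
                ):
                    if best is None or rank.get(r.cls, 0) > rank.get(best, 0):
                        best = r.cls
            if best is not None:
                out[(strain, pc.source.name)] = best
    return out


def unique_cuts(
    projected_by_strain: Mapping[str, Sequence[ProjectedCut]],
    removed_raw_by_strain: Mapping[str, Sequence[ProjectedCut]],
) -> dict[str, list[Annotation]]:
    """Strictly strain-unique CUTs: no other strain carries a final OR a
    raw-but-removed segment overlapping the CUT's columns (same strand)."""
    strains = list(projected_by_strain)
    out: dict[str, list[Annotation]] = {s: [] for s in strains}
    for s in strains:
        others = [o for o in strains if o != s]
        for pc in projected_by_strain[s]:
            if not pc.columns.size:
                continue
            clash = False
            for o in others:
                candidates = list(projected_by_strain[o]) + list(
                    removed_raw_by_strain.get(o, [])
                )
                for opc in candidates:
                    if (
                        opc.source.strand == pc.source.strand
                        and opc.columns.size
                        and opc.col_start < pc.col_end
                        and opc.col_end > pc.col_start
                    ):
                        clash = True
                        break
                if clash:
                    break
            if not clash:
                out[s].append(pc.source)
    return out


def percent_identity(
    amap: AlignmentMap,
    columns: np.ndarray,
    strains: Sequence[str] | None = None,
) -> float:
    """Mean pairwise identity (0-100) over the given columns.  A pair counts
    as comparable when at least one strain has a base; it is identical only
    when both have the same base, so gaps score as mismatches."""
    strains = list(strains or amap.strains)
    cols = np.asarray(columns, dtype=np.int64)
    if cols.size == 0:
        raise ValueError("no columns to compare")
    bases = np.stack([amap.col_base[s][cols] for s in strains])
    num = 0
    den = 0
    n = len(strains)
    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = bases[i], bases[j]
            either = (bi > 0) | (bj > 0)
            both_eq = (bi > 0) & (bi == bj)
            num += int(both_eq.sum())
            den += int(either.sum())
    if den == 0:
        raise ValueError("no comparable strain pairs over these columns")
    return 100.0 * num / den


def promoter_window(cut: Annotation, upstream: int, genome: Genome | None = None) -> Annotation:
    """Strand-aware window of ``upstream`` bp immediately 5' of the CUT TSS."""
    if cut.strand == "+":
        start, end = cut.start - upstream, cut.start
    else:
        start, end = cut.end, cut.end + upstream
    if genome is not None:
        size = genome.chrom_sizes[cut.chrom]
        start, end = max(0, start), min(size, end)
    if end <= start:
        raise ValueError("promoter window collapsed at chromosome edge")
    return Annotation(cut.chrom, start, end, cut.strand, name=f"{cut.name}_prom{upstream}")


def randomized_conservation(
    genomes: Mapping[str, Genome],
    length_multisets: Mapping[str, Sequence[int]],
    amap: AlignmentMap,
    iterations: int = 200,
    seed: int = 0,
    max_gap_fraction: float = 0.25,
    fourx_threshold: float = 3.5,
) -> np.ndarray:
    """Null counts of top-class (all-strain) regions when every strain's
    CUTs are re-placed uniformly at random; 200 iterations by default."""
    from .overlaps import sample_random_regions

    rng = np.random.default_rng(seed)
    counts = np.empty(iterations, dtype=np.int64)
    top = _class_label(len(amap.strains), len(amap.strains))
    for it in range(iterations):
        projected = {}
        for s in amap.strains:
            rand = sample_random_regions(genomes[s], length_multisets[s], rng)
            projected[s], _ = project(rand, amap, s, max_gap_fraction)
        regions = conservation_call(projected, None, fourx_threshold, with_members=False)
        counts[it] = sum(1 for r in regions if r.cls == top)
    return counts
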