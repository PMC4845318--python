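"""Per-nucleotide coverage and rrp6-delta/WT fold-change tracks.

Coverage is normalized by tens of millions of mapped reads, averaged across
biological replicates, and converted to a per-nucleotide fold-change track
with a Laplace (+1) prior so that uncovered positions give fold change 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import Annotation, Genome, STRANDS, UNSTRANDED, read_dense, write_dense

NORMALIZATION_UNIT = 1e7  # "tens of millions of mapped reads"


@dataclass
class CoverageTrack:
    """Dense per-(chromosome, strand) signal with normalization metadata."""

    genome: Genome
    data: dict[tuple[str, str], np.ndarray]
    mapped_read_count: int = 0
    normalized: bool = False
    bias_corrected: bool = False
    strands: tuple[str, ...] = STRANDS

    @classmethod
    def zeros(cls, genome: Genome, strands: tuple[str, ...] = STRANDS, **kw) -> "CoverageTrack":
        data = {
            (c, s): np.zeros(n)
            for c, n in genome.chrom_sizes.items()
            for s in strands
        }
        return cls(genome, data, strands=strands, **kw)

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        return self.data[key]

    def array(self, chrom: str, strand: str = ".") -> np.ndarray:
        """Strand-tolerant lookup: unstranded tracks answer for any strand."""
        if (chrom, strand) in self.data:
            return self.data[(chrom, strand)]
        if (chrom, ".") in self.data:
            return self.data[(chrom, ".")]
        raise KeyError((chrom, strand))

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.genome,
            {k: v.copy() for k, v in self.data.items()},
            self.mapped_read_count,
            self.normalized,
            self.bias_corrected,
            self.strands,
        )

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def mean_over(self, ann: Annotation) -> float:
        return float(self.array(ann.chrom, ann.strand)[ann.start : ann.end].mean())

    def nonzero_values(self) -> np.ndarray:
        vals = np.concatenate([v for v in self.data.values()])
        return vals[vals > 0]

    # -- I/O: one bedGraph per strand -----------------------------------
    @classmethod
    def from_bedgraphs(
        cls, genome: Genome, paths_by_strand: Mapping[str, str], mapped_read_count: int = 0,
        normalized: bool = False,
    ) -> "CoverageTrack":
        strands = tuple(paths_by_strand)
        data = {}
        for strand, path in paths_by_strand.items():
            arrays = read_dense(path, genome)
            for chrom, arr in arrays.items():
                data[(chrom, strand)] = arr
        return cls(genome, data, mapped_read_count, normalized=normalized, strands=strands)

    def to_bedgraphs(self, paths_by_strand: Mapping[str, str]) -> None:
        for strand, path in paths_by_strand.items():
            write_dense(
                {c: self.data[(c, strand)] for c in self.genome.chrom_sizes}, path
            )


@dataclass
class FoldChangeTrack:
    """f_i = (R_i + 1) / (W_i + 1), replicate-averaged rrp6-delta over WT."""

    genome: Genome
    data: dict[tuple[str, str], np.ndarray]
    strands: tuple[str, ...] = STRANDS

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        return self.data[key]


def coverage_from_reads(read_intervals: Sequence[Annotation], genome: Genome) -> CoverageTrack:
    """Pile up stranded read intervals into per-nucleotide coverage."""
    track = CoverageTrack.zeros(genome)
    for r in read_intervals:
        genome.check_interval(r)
        track.data[(r.chrom, r.strand)][r.start : r.end] += 1
    track.mapped_read_count = len(read_intervals)
    return track


def normalize(track: CoverageTrack, mapped_read_count: int | None = None) -> CoverageTrack:
    """Divide by (mapped reads / 1e7).  Refuses double normalization."""
    if track.normalized:
        raise ValueError("track is already normalized")
    n = track.mapped_read_count if mapped_read_count is None else mapped_read_count
    if n <= 0:
        raise ValueError("mapped_read_count must be positive to normalize")
    out = track.copy()
    out.mapped_read_count = n
    factor = n / NORMALIZATION_UNIT
    for k in out.data:
        out.data[k] = out.data[k] / factor
    out.normalized = True
    return out


def bias_correct(track: CoverageTrack, weights: CoverageTrack) -> CoverageTrack:
    """Divide coverage by per-position weights (first-nucleotide bias and/or
    mappability).  Positions with weight 0 must carry no coverage."""
    out = track.copy()
    for k in out.data:
        w = weights.array(*k)
        v = out.data[k]
        bad = (w <= 0) & (v > 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"zero weight with nonzero coverage at {k[0]}:{i}")
        with np.errstate(divide="ignore", invalid="ignore"):
            out.data[k] = np.where(w > 0, v / np.where(w > 0, w, 1.0), 0.0)
    out.bias_corrected = True
    return out


def first_nucleotide_weights(
    genome: Genome, read_starts: Sequence[Annotation]
) -> CoverageTrack:
    """Per-position weight = (frequency of the genomic base among read 5'
    starts) / (genome-wide frequency of that base).  Requires sequences."""
    if genome.sequences is None:
        raise ValueError("genome sequences required for first-nucleotide weights")
    base_idx = {b: i for i, b in enumerate("ACGT")}
    genome_counts = np.zeros(4)
    for seq in genome.sequences.values():
        for b, i in base_idx.items():
            genome_counts[i] += seq.count(b)
    start_counts = np.zeros(4)
    for r in read_starts:
        pos = r.start if r.strand == "+" else r.end - 1
        b = genome.sequences[r.chrom][pos]
        if b in base_idx:
            start_counts[base_idx[b]] += 1
    gf = genome_counts / genome_counts.sum()
    sf = start_counts / max(start_counts.sum(), 1)
    ratio = np.where(gf > 0, sf / np.where(gf > 0, gf, 1.0), 1.0)
    weights = CoverageTrack.zeros(genome)
    for chrom, seq in genome.sequences.items():
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        w = np.ones(len(seq))
        for b, i in base_idx.items():
            w[codes == ord(b)] = ratio[i] if ratio[i] > 0 else 1.0
        for s in weights.strands:
            weights.data[(chrom, s)] = w.copy()
    return weights


def average_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Arithmetic per-position mean across replicate tracks."""
    if not tracks:
        raise ValueError("need at least one replicate")
    first = tracks[0]
    for t in tracks[1:]:
        if t.genome.chrom_sizes != first.genome.chrom_sizes:
            raise ValueError("replicate tracks disagree on chromosome sizes")
        if t.normalized != first.normalized:
            raise ValueError("mixing normalized and raw replicates")
    out = first.copy()
    for k in out.data:
        out.data[k] = np.mean([t.data[k] for t in tracks], axis=0)
    out.mapped_read_count = int(round(np.mean([t.mapped_read_count for t in tracks])))
    return out


def fold_change(rrp6_avg: CoverageTrack, wt_avg: CoverageTrack) -> FoldChangeTrack:
    """Per-nucleotide (R+1)/(W+1); equals 1 wherever both coverages are 0."""
    if rrp6_avg.genome.chrom_sizes != wt_avg.genome.chrom_sizes:
        raise ValueError("rrp6 and WT tracks disagree on chromosome sizes")
    data = {}
    for k in rrp6_avg.data:
        data[k] = (rrp6_avg.data[k] + 1.0) / (wt_avg.data[k] + 1.0)
    return FoldChangeTrack(rrp6_avg.genome, data, strands=rrp6_avg.strands)


def fold_change_pipeline(
    wt_reps: Sequence[CoverageTrack],
    rrp6_reps: Sequence[CoverageTrack],
    bias_weights: CoverageTrack | None = None,
) -> tuple[FoldChangeTrack, CoverageTrack, CoverageTrack]:
    """Normalize each replicate, optionally bias-correct, average, and take
    the fold change.  Returns (fold change, rrp6 average, WT average)."""

    def prep(reps):
        done = []
        for t in reps:
            t = t if t.normalized else normalize(t)
            if bias_weights is not None:
                t = bias_correct(t, bias_weights)
            done.append(t)
        return average_replicates(done)

    wt_avg = prep(wt_reps)
    rrp6_avg = prep(rrp6_reps)
    return fold_change(rrp6_avg, wt_avg), rrp6_avg, wt_avg
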