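"""Filter cascade turning raw HMM segments into final CUT annotations.

Order: remove segments overlapping known exosome-target ncRNAs (snRNA,
snoRNA, rRNA) and genotype-difference regions; merge same-strand segments
within 450 bp; drop regions whose mean rrp6-delta coverage falls below the
upper two-thirds of all nonzero per-nucleotide values; drop regions shorter
than 100 nt.  Removed raw segments are kept: they are needed to prune
external comparison catalogs and to rescue conservation calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .coverage import CoverageTrack
from .genomic_io import Annotation

DEFAULT_EXCLUSION_CLASSES = frozenset({"snRNA", "snoRNA", "rRNA"})


@dataclass
class RefinementConfig:
    merge_gap: int = 450
    min_length: int = 100
    coverage_quantile: float = 1.0 / 3.0
    exclusion_classes: frozenset[str] = DEFAULT_EXCLUSION_CLASSES
    genotype_exclusion: tuple[Annotation, ...] = ()

    def __post_init__(self):
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if not (0.0 < self.coverage_quantile < 1.0):
            raise ValueError("coverage_quantile must be in (0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class RefinedSet:
    final: list[Annotation]
    removed_raw: list[Annotation]
    coverage_threshold: float = float("nan")


def _trees(anns: Sequence[Annotation]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for a in anns:
        trees.setdefault((a.chrom, a.strand), IntervalTree()).addi(a.start, a.end, a)
    return trees


def exclude_overlapping(
    raw: Sequence[Annotation],
    exclusions: Sequence[Annotation],
    same_strand: bool = True,
) -> tuple[list[Annotation], list[Annotation]]:
    """Split segments into (kept, removed); removed iff >=1 bp overlap with
    any exclusion feature (same-strand by default)."""
    trees = _trees(exclusions)
    kept, removed = [], []
    for a in raw:
        keys = [(a.chrom, a.strand)] if same_strand else [
            (a.chrom, s) for s in ("+", "-", ".")
        ]
        hit = any(trees.get(k) and trees[k].overlap(a.start, a.end) for k in keys)
        (removed if hit else kept).append(a)
    return kept, removed


def merge_adjacent(segments: Sequence[Annotation], merge_gap: int = 450) -> list[Annotation]:
    """Transitively merge same-strand, same-chromosome segments whose gap is
    <= merge_gap; output gaps are all > merge_gap.  Idempotent."""
    by_key: dict[tuple[str, str], list[Annotation]] = {}
    for a in sorted(segments, key=lambda x: (x.chrom, x.strand, x.start, x.end)):
        by_key.setdefault((a.chrom, a.strand), []).append(a)
    out = []
    for (chrom, strand), group in sorted(by_key.items()):
        cur_start, cur_end = group[0].start, group[0].end
        idx = 0
        for a in group[1:]:
            if a.start - cur_end <= merge_gap:
                cur_end = max(cur_end, a.end)
            else:
                out.append(
                    Annotation(chrom, cur_start, cur_end, strand,
                               name=f"CUT_{chrom}{strand}_{idx}", feature_class="CUT")
                )
                idx += 1
                cur_start, cur_end = a.start, a.end
        out.append(
            Annotation(chrom, cur_start, cur_end, strand,
                       name=f"CUT_{chrom}{strand}_{idx}", feature_class="CUT")
        )
    return sorted(out, key=lambda a: (a.chrom, a.start, a.end, a.strand))


def coverage_threshold(rrp6_avg: CoverageTrack, coverage_quantile: float = 1.0 / 3.0) -> float:
    """Smallest value of the upper (1 - q) fraction of all nonzero
    per-nucleotide rrp6-delta values, genome-wide over both strands.

    The lower q fraction (floor(n*q) order statistics) is discarded and the
    threshold is the next value up, so on nonzero values {1..9} with
    q = 1/3 the threshold is 4, and as q -> 0 it falls to the minimum.
    """
    nz = rrp6_avg.nonzero_values()
    if nz.size == 0:
        raise ValueError("rrp6-delta track is all zero; no coverage threshold")
    nz = np.sort(nz)
    idx = min(int(np.floor(nz.size * coverage_quantile)), nz.size - 1)
    return float(nz[idx])


def coverage_filter(
    cuts: Sequence[Annotation],
    rrp6_avg: CoverageTrack,
    coverage_quantile: float = 1.0 / 3.0,
) -> tuple[list[Annotation], list[Annotation], float]:
    """Remove CUTs whose mean rrp6-delta coverage is strictly below the
    genome-wide threshold; returns (kept, removed, threshold)."""
    tau = coverage_threshold(rrp6_avg, coverage_quantile)
    kept, removed = [], []
    for a in cuts:
        (removed if rrp6_avg.mean_over(a) < tau else kept).append(a)
    return kept, removed, tau


def length_filter(
    cuts: Sequence[Annotation], min_length: int = 100
) -> tuple[list[Annotation], list[Annotation]]:
    """Keep annotations of length >= min_length ("less than" is strict)."""
    kept = [a for a in cuts if a.length >= min_length]
    removed = [a for a in cuts if a.length < min_length]
    return kept, removed


def refine(
    raw: Sequence[Annotation],
    config: RefinementConfig,
    rrp6_avg: CoverageTrack,
    exclusions: Sequence[Annotation] = (),
) -> RefinedSet:
    """Full cascade: exclude -> merge -> coverage filter -> length filter.

    ``exclusions`` are ncRNA annotations; only classes named in the config
    are applied, plus any genotype-difference intervals.  All raw segments
    dropped anywhere in the cascade are returned in ``removed_raw``.
    """
    active_exclusions = [
        a for a in exclusions if a.feature_class in config.exclusion_classes
    ] + list(config.genotype_exclusion)
    kept, removed_raw = exclude_overlapping(raw, active_exclusions)
    merged = merge_adjacent(kept, config.merge_gap)
    covered, low_cov, tau = coverage_filter(merged, rrp6_avg, config.coverage_quantile)
    final, short = length_filter(covered, config.min_length)
    # raw segments falling inside a merged-then-removed region also count as removed
    dropped_regions = low_cov + short
    if dropped_regions:
        _, raw_in_dropped = exclude_overlapping(kept, dropped_regions)
        removed_raw = removed_raw + raw_in_dropped
    final = [
        a.with_(name=f"CUT_{i+1:04d}", feature_class="CUT")
        for i, a in enumerate(sorted(final, key=lambda x: (x.chrom, x.start, x.end)))
    ]
    return RefinedSet(final=final, removed_raw=removed_raw, coverage_threshold=tau)
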