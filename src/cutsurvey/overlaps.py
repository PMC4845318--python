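"""Annotation-set comparison and the shared statistical tests.

Two annotations match when, on the same chromosome and strand, their overlap
is at least 25% of the length of either one.  Significance of an observed
match count is judged against a randomization null: regions with the same
length multiset are placed uniformly 200 times and the observed count is
called significant beyond two standard deviations above the null mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genomic_io import Annotation, Genome


@dataclass
class OverlapResult:
    matched_a: list[Annotation]
    matched_b: list[Annotation]
    n_a: int
    n_b: int
    min_frac: float

    @property
    def n_matched_a(self) -> int:
        return len(self.matched_a)

    @property
    def n_matched_b(self) -> int:
        return len(self.matched_b)


@dataclass
class NullDistribution:
    samples: np.ndarray
    z_threshold: float = 2.0

    @property
    def iterations(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples))

    def is_significant(self, observed: int) -> bool:
        """One-sided: observed beyond z_threshold SDs above the null mean."""
        return observed > self.mean + self.z_threshold * self.sd


def overlap_match(
    a_set: Sequence[Annotation],
    b_set: Sequence[Annotation],
    min_frac: float = 0.25,
) -> OverlapResult:
    """Symmetric reciprocal-fraction matching: (a, b) match iff overlap_bp
    >= min_frac * len(a) OR >= min_frac * len(b)."""
    if not (0.0 < min_frac <= 1.0):
        raise ValueError("min_frac must be in (0, 1]")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for b in b_set:
        trees.setdefault((b.chrom, b.strand), IntervalTree()).addi(b.start, b.end, b)
    matched_a, matched_b = [], set()
    for a in a_set:
        tree = trees.get((a.chrom, a.strand))
        if tree is None:
            continue
        hit = False
        for iv in tree.overlap(a.start, a.end):
            b = iv.data
            ov = a.overlap_bp(b)
            if ov >= min_frac * a.length or ov >= min_frac * b.length:
                hit = True
                matched_b.add(b)
        if hit:
            matched_a.append(a)
    return OverlapResult(
        matched_a=matched_a,
        matched_b=sorted(matched_b, key=lambda x: (x.chrom, x.start, x.end)),
        n_a=len(a_set),
        n_b=len(b_set),
        min_frac=min_frac,
    )


def sample_random_regions(
    genome: Genome,
    length_multiset: Sequence[int],
    rng: np.random.Generator | int,
) -> list[Annotation]:
    """One uniformly placed region per input length; strand assigned + or -
    with probability 1/2.  Placement is uniform over all valid (chrom, start)
    pairs, weighting chromosomes by the number of valid starts."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms])
    out = []
    for i, L in enumerate(length_multiset):
        valid = sizes - L + 1
        if np.all(valid <= 0):
            raise ValueError(f"length {L} exceeds every chromosome")
        w = np.clip(valid, 0, None).astype(float)
        ci = rng.choice(len(chroms), p=w / w.sum())
        start = int(rng.integers(0, valid[ci]))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(
            Annotation(chroms[ci], start, start + L, strand, name=f"rand_{i}")
        )
    return out


def overlap_null(
    b_set: Sequence[Annotation],
    genome: Genome,
    length_multiset: Sequence[int],
    iterations: int = 200,
    seed: int | np.random.Generator = 0,
    min_frac: float = 0.25,
) -> NullDistribution:
    """Null distribution of matched-region counts for random placements."""
    if iterations < 2:
        raise ValueError("need at least 2 iterations")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    samples = np.empty(iterations)
    for i in range(iterations):
        rand = sample_random_regions(genome, length_multiset, rng)
        samples[i] = overlap_match(rand, b_set, min_frac).n_matched_a
    return NullDistribution(samples=samples)


def hypergeometric_p(population: int, successes: int, draws: int, observed: int) -> float:
    """Upper-tail P[X >= observed] for X ~ Hypergeom(population, successes, draws)."""
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValueError("inconsistent hypergeometric counts")
    if not (0 <= observed <= min(successes, draws)):
        raise ValueError("observed outside [0, min(successes, draws)]")
    return float(stats.hypergeom.sf(observed - 1, population, successes, draws))


def ks_two_sided(sample_x: Sequence[float], sample_y: Sequence[float]) -> tuple[float, float]:
    """Two-sample, two-sided Kolmogorov-Smirnov statistic and p-value."""
    x, y = np.asarray(sample_x, float), np.asarray(sample_y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires nonempty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def prune_catalog(
    catalog: Sequence[Annotation], removed_raw: Sequence[Annotation]
) -> list[Annotation]:
    """Drop external catalog entries overlapping our removed raw segments
    (any overlap, same strand), mirroring the pruning applied before the
    catalog comparisons."""
    from .refine import exclude_overlapping

    kept, _ = exclude_overlapping(catalog, removed_raw)
    return kept
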