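"""Nucleosome-occupancy metagene averaging and TSS/TTS distance histograms.

Metagene profiles average a signal track over a 500 bp window centered on
each anchor (offsets -250..+249); minus-strand windows are flipped so that
negative offsets are always upstream.  Distance histograms report, for each
query site, the signed distance to the nearest same-strand reference site
(positive = reference downstream of the query in its strand orientation),
retained when within +/-50 bp and binned at 5 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack


@dataclass
class MetageneProfile:
    offsets: np.ndarray          # window offsets relative to the anchor
    mean: np.ndarray             # mean signal per offset
    n: np.ndarray                # anchors contributing per offset

    def minimum(self) -> tuple[int, float]:
        """(offset, value) of the profile minimum."""
        i = int(np.nanargmin(self.mean))
        return int(self.offsets[i]), float(self.mean[i])


def metagene(
    track: CoverageTrack,
    anchors: Sequence[tuple[str, int, str]],
    window: int = 500,
    center: bool = True,
) -> MetageneProfile:
    """Average a track over strand-oriented windows around anchors.

    ``anchors`` are (chrom, position, strand).  With ``center`` (default)
    offsets run -window//2 .. window//2 - 1; otherwise 0 .. window-1
    (window starting at the anchor).  Edge anchors contribute partial
    windows.  Unstranded tracks (pseudo-strand ".") serve both strands.
    """
    if len(anchors) == 0:
        raise ValueError("metagene requires at least one anchor")
    lo = -(window // 2) if center else 0
    offsets = np.arange(lo, lo + window)
    total = np.zeros(window)
    count = np.zeros(window, dtype=np.int64)
    for chrom, pos, strand in anchors:
        arr = track.array(chrom, strand)
        n = arr.shape[0]
        if strand == "-":
            genome_pos = pos - offsets
        else:
            genome_pos = pos + offsets
        valid = (genome_pos >= 0) & (genome_pos < n)
        total[valid] += arr[genome_pos[valid]]
        count[valid] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MetageneProfile(offsets=offsets, mean=mean, n=count)


def tss_anchors(annotations, which: str = "TSS") -> list[tuple[str, int, str]]:
    """Anchor list at the 5' (TSS) or 3' (TTS) ends of stranded intervals."""
    out = []
    for a in annotations:
        if which == "TSS":
            pos = a.start if a.strand == "+" else a.end - 1
        elif which == "TTS":
            pos = a.end - 1 if a.strand == "+" else a.start
        else:
            raise ValueError("which must be 'TSS' or 'TTS'")
        out.append((a.chrom, pos, a.strand))
    return out


@dataclass
class DistanceHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    distances: np.ndarray        # retained signed distances
    n_query: int

    @property
    def fraction_within(self) -> float:
        """Fraction of query sites within max_dist of a reference site."""
        return len(self.distances) / self.n_query if self.n_query else 0.0


def nearest_distance_histogram(
    query_sites: Sequence[tuple[str, int, str]],
    reference_sites: Sequence[tuple[str, int, str]],
    max_dist: int = 50,
    bin_width: int = 5,
) -> DistanceHistogram:
    """Signed nearest same-strand distances, query -> reference.

    Positive distances mean the reference lies downstream of the query in
    the query's strand orientation; ties between equally near references
    break toward the downstream one.
    """
    if len(reference_sites) == 0:
        raise ValueError("empty reference site list")
    refs: dict[tuple[str, str], np.ndarray] = {}
    for chrom, pos, strand in reference_sites:
        refs.setdefault((chrom, strand), []).append(pos)  # type: ignore[arg-type]
    refs = {k: np.sort(np.asarray(v)) for k, v in refs.items()}
    kept = []
    for chrom, pos, strand in query_sites:
        arr = refs.get((chrom, strand))
        if arr is None:
            continue
        i = np.searchsorted(arr, pos)
        cands = [arr[j] for j in (i - 1, i) if 0 <= j < arr.size]
        if not cands:
            continue
        # signed distance in strand orientation
        signed = [(r - pos) if strand == "+" else (pos - r) for r in cands]
        best = min(signed, key=lambda d: (abs(d), -d))
        if abs(best) <= max_dist:
            kept.append(best)
    edges = np.arange(-max_dist, max_dist + bin_width, bin_width)
    counts, _ = np.histogram(kept, bins=edges)
    return DistanceHistogram(
        bin_edges=edges,
        counts=counts,
        distances=np.asarray(kept),
        n_query=len(query_sites),
    )


def filter_tss_clusters(
    clusters: pd.DataFrame,
    categories: Sequence[str] = ("A", "B", "I"),
    min_fold: float = 1.5,
    category_col: str = "category",
    fold_col: str = "fold",
) -> pd.DataFrame:
    """Keep TSS clusters in the named categories with fold change >= min_fold
    (inclusive)."""
    for col in (category_col, fold_col):
        if col not in clusters.columns:
            raise ValueError(f"missing column {col!r} in TSS cluster table")
    mask = clusters[category_col].isin(list(categories)) & (
        clusters[fold_col] >= min_fold
    )
    return clusters.loc[mask].copy()
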