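"""Gene-CUT architecture: NFR annotation, pair classification, expression.

NFRs are fixed windows: the 5' NFR spans TSS-200..TSS and the 3' NFR spans
TTS-100..TTS+100, both strand-aware and clipped at chromosome edges.  A CUT
shares a gene NFR when its 5' NFR overlaps the gene NFR by >= 50% of the
gene NFR's length and >= 100 bp.  Antisense (convergent) pairs: CUT 5' NFR
x gene 3' NFR, opposite strands, CUT body overlapping the gene.  Divergent
pairs: shared 5' NFR, opposite strands, bodies disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genomic_io import Annotation, Genome
from .overlaps import hypergeometric_p, ks_two_sided

NFR5_UPSTREAM = 200
NFR3_FLANK = 100


@dataclass
class NfrAnnotation:
    parent: Annotation
    kind: str                   # "NFR5" | "NFR3"
    interval: Annotation
    clipped: bool = False


def annotate_nfrs(
    features: Sequence[Annotation],
    kinds: Sequence[str] = ("NFR5", "NFR3"),
    genome: Genome | None = None,
) -> list[NfrAnnotation]:
    """Strand-aware NFR windows for each feature.

    Features are transcripts (UTR-inclusive for genes): TSS is the 5' end,
    TTS the 3' end in the feature's orientation.
    """
    out = []
    for f in features:
        windows = {}
        if f.strand == "+":
            windows["NFR5"] = (f.start - NFR5_UPSTREAM, f.start)
            windows["NFR3"] = (f.end - NFR3_FLANK, f.end + NFR3_FLANK)
        else:
            windows["NFR5"] = (f.end, f.end + NFR5_UPSTREAM)
            windows["NFR3"] = (f.start - NFR3_FLANK, f.start + NFR3_FLANK)
        for kind in kinds:
            start, end = windows[kind]
            clipped = False
            if start < 0:
                start, clipped = 0, True
            if genome is not None:
                size = genome.chrom_sizes[f.chrom]
                if end > size:
                    end, clipped = size, True
            if end <= start:
                continue
            out.append(
                NfrAnnotation(
                    parent=f,
                    kind=kind,
                    interval=Annotation(
                        f.chrom, start, end, f.strand,
                        name=f"{f.name}_{kind}", feature_class=kind,
                    ),
                    clipped=clipped,
                )
            )
    return out


@dataclass
class GeneCutPair:
    gene: Annotation
    cut: Annotation
    configuration: str          # "antisense" | "divergent" | "same_sense"
    overlap_bp: int
    overlap_frac: float         # of the gene NFR


def _nfr_sharing(cut_nfr: Annotation, gene_nfr: Annotation, min_frac: float, min_bp: int):
    ov = cut_nfr.overlap_bp(gene_nfr)
    if ov >= min_frac * gene_nfr.length and ov >= min_bp:
        return ov, ov / gene_nfr.length
    return None


def classify_pairs(
    cut_nfr5s: Sequence[NfrAnnotation],
    gene_nfrs: Sequence[NfrAnnotation],
    min_frac: float = 0.5,
    min_bp: int = 100,
) -> list[GeneCutPair]:
    """Classify gene-CUT NFR sharing into antisense and divergent pairs.

    Same-sense overlapping configurations are reported with configuration
    ``"same_sense"`` so callers can exclude them from expression statistics.
    """
    pairs = []
    for cn in cut_nfr5s:
        if cn.kind != "NFR5":
            continue
        cut = cn.parent
        for gn in gene_nfrs:
            gene = gn.parent
            if gene.chrom != cut.chrom:
                continue
            share = _nfr_sharing(cn.interval, gn.interval, min_frac, min_bp)
            if share is None:
                continue
            ov, frac = share
            if gene.strand == cut.strand:
                if cut.overlap_bp(gene) > 0:
                    pairs.append(GeneCutPair(gene, cut, "same_sense", ov, frac))
                continue
            body_overlap = cut.overlap_bp(gene) > 0
            if gn.kind == "NFR3" and body_overlap:
                pairs.append(GeneCutPair(gene, cut, "antisense", ov, frac))
            elif gn.kind == "NFR5" and not body_overlap:
                pairs.append(GeneCutPair(gene, cut, "divergent", ov, frac))
    return sorted(
        pairs, key=lambda p: (p.gene.chrom, p.gene.start, p.cut.start, p.configuration)
    )


def divergent_gene_gene_pairs(
    genes: Sequence[Annotation],
    min_frac: float = 0.5,
    min_bp: int = 100,
    genome: Genome | None = None,
) -> list[GeneCutPair]:
    """Head-to-head gene pairs sharing a 5' NFR (same rule as gene-CUT
    divergent pairs); the control set for the divergent-CUT comparison."""
    nfr5s = annotate_nfrs(genes, kinds=("NFR5",), genome=genome)
    pairs = []
    for i, a in enumerate(nfr5s):
        for b in nfr5s[i + 1 :]:
            ga, gb = a.parent, b.parent
            if ga == gb or ga.chrom != gb.chrom or ga.strand == gb.strand:
                continue
            share = _nfr_sharing(a.interval, b.interval, min_frac, min_bp)
            if share is None:
                continue
            if ga.overlap_bp(gb) == 0:
                ov, frac = share
                pairs.append(GeneCutPair(ga, gb, "divergent", ov, frac))
    return pairs


def summarize_expression(
    genes: Sequence[Annotation],
    tracks: Mapping[str, CoverageTrack],
    exclusion_cuts: Sequence[Annotation] = (),
    expressed_floor: float = 0.0,
    cds_by_gene: Mapping[str, Annotation] | None = None,
) -> pd.DataFrame:
    """Per-gene mean coverages and derived metrics.

    ``tracks`` maps metric names ("WT", "rrp6", "nascent") to normalized,
    replicate-averaged tracks.  Genes with a same-sense CUT overlapping
    >= 50% of the CDS are excluded; "expressed" means mean WT coverage
    strictly above ``expressed_floor``.  log2 fold change uses the +1 prior
    on the mean coverages; repression = nascent - WT where available.
    """
    rows = []
    for g in genes:
        cds = (cds_by_gene or {}).get(g.name, g)
        same_sense_hit = any(
            c.strand == g.strand and c.chrom == g.chrom
            and c.overlap_bp(cds) >= 0.5 * cds.length
            for c in exclusion_cuts
        )
        if same_sense_hit:
            continue
        row = {"gene": g.name, "chrom": g.chrom, "start": g.start, "end": g.end,
               "strand": g.strand}
        for metric, track in tracks.items():
            row[metric] = track.mean_over(g)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if "WT" in df:
        df["expressed"] = df["WT"] > expressed_floor
    if "WT" in df and "rrp6" in df:
        df["log2_fc"] = np.log2((df["rrp6"] + 1.0) / (df["WT"] + 1.0))
    if "WT" in df and "nascent" in df:
        df["repression"] = df["nascent"] - df["WT"]
    return df.set_index("gene")


DEFAULT_METRICS = ("WT", "rrp6", "log2_fc", "nascent")


def compare_groups(
    summary: pd.DataFrame,
    group_sets: Mapping[str, Sequence[str]],
    metrics: Sequence[str] = DEFAULT_METRICS,
    ns_alpha: float = 0.1,
) -> pd.DataFrame:
    """KS-compare each gene group against the all-expressed-genes background.

    Returns one row per (group, metric) with the two-sided KS D and p,
    group/background medians and quartiles, and an ``ns`` flag for
    p >= ``ns_alpha``.  Genes are deduplicated within each group.
    """
    bg = summary[summary["expressed"]] if "expressed" in summary else summary
    rows = []
    for gname, members in group_sets.items():
        members = sorted(set(members))
        sub = bg.loc[bg.index.intersection(members)]
        if len(sub) < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 expressed genes")
        for metric in metrics:
            if metric not in bg.columns:
                continue
            D, p = ks_two_sided(sub[metric].to_numpy(), bg[metric].to_numpy())
            q1, med, q3 = np.percentile(sub[metric], [25, 50, 75])
            bq1, bmed, bq3 = np.percentile(bg[metric], [25, 50, 75])
            rows.append(
                {
                    "group": gname, "metric": metric, "n": len(sub),
                    "n_background": len(bg), "D": D, "p": p, "ns": p >= ns_alpha,
                    "median": med, "q1": q1, "q3": q3,
                    "background_median": bmed, "background_q1": bq1, "background_q3": bq3,
                }
            )
    return pd.DataFrame(rows)


def enrichment_4x_in_nfr(
    cuts: Sequence[Annotation],
    nfr_origin_flags: Mapping[str, bool],
    conserved_flags: Mapping[str, bool],
) -> float:
    """Upper-tail hypergeometric p for enrichment of NFR-origin CUTs within
    the top conservation class."""
    names = [c.name for c in cuts]
    population = len(names)
    successes = sum(bool(nfr_origin_flags.get(n, False)) for n in names)
    draws = sum(bool(conserved_flags.get(n, False)) for n in names)
    observed = sum(
        bool(nfr_origin_flags.get(n, False)) and bool(conserved_flags.get(n, False))
        for n in names
    )
    return hypergeometric_p(population, successes, draws, observed)


def nfr_origin_flags(
    cuts: Sequence[Annotation],
    genes: Sequence[Annotation],
    min_frac: float = 0.5,
    min_bp: int = 100,
    genome: Genome | None = None,
) -> dict[str, bool]:
    """Whether each CUT originates from (shares) a gene 5' or 3' NFR."""
    cut_nfr5s = annotate_nfrs(cuts, kinds=("NFR5",), genome=genome)
    gene_nfrs = annotate_nfrs(genes, kinds=("NFR5", "NFR3"), genome=genome)
    flags = {c.name: False for c in cuts}
    for cn in cut_nfr5s:
        for gn in gene_nfrs:
            if cn.parent.chrom != gn.parent.chrom:
                continue
            if _nfr_sharing(cn.interval, gn.interval, min_frac, min_bp) is not None:
                flags[cn.parent.name] = True
                break
    return flags
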