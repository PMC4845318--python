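"""Synthetic worlds with the statistical structure the pipeline assumes.

A common ancestor genome acquires per-strain substitutions and indels,
defining a master column space (the truth behind the MAF).  Genes (with
UTRs) and CUTs are planted in master coordinates: CUTs follow a lognormal
length distribution (median ~400 nt), are elevated 2-8x in rrp6-delta over
a WT baseline, and are assigned an architecture (divergent from a gene's
5' NFR, antisense from its 3' NFR, or NFR-free) and a conservation pattern
(present in 4, 3, 2 or 1 of the 4 strains, with per-strain boundary
jitter).  Coverage tracks add read-length-correlated Poisson or negative-
binomial counting noise; nucleosome tracks carry 5' NFR dips at gene and
CUT TSSs (and gene TTSs) but none at CUT 3' ends; divergent-paired genes
are expression-shifted and antisense-paired genes are reduced at steady
state but not in the nascent (NET-seq-like) track.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genomic_io import Annotation, Genome, MafBlock, MafSeq, write_annotations, write_maf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    seed: int = 0
    strains: tuple[str, ...] = ("S1", "S2", "S3", "S4")
    n_chroms: int = 2
    chrom_length: int = 250_000
    n_genes: int = 200
    n_cuts: int = 100
    n_ncrnas: int = 10
    # CUT signal
    cut_length_median: float = 400.0
    cut_length_sigma: float = 0.45
    cut_fold_range: tuple[float, float] = (2.0, 8.0)
    cut_wt_level: float = 10.0
    # gene expression
    gene_expr_mean: float = 40.0
    gene_expr_sigma: float = 0.7
    baseline: float = 0.1
    # architecture mix and effects
    frac_divergent: float = 0.25
    frac_antisense: float = 0.25
    divergent_shift_log2: float = 1.0
    antisense_reduction: float = 0.5
    # conservation patterns
    frac_4x: float = 0.55
    frac_3x: float = 0.15
    frac_2x: float = 0.10
    rescue_fraction: float = 0.3
    jitter_sd: float = 20.0
    # alignment divergence
    substitution_rate: float = 0.01
    indel_rate: float = 2e-4
    indel_mean_length: float = 3.0
    # coverage noise: per-base counting is Poisson; "nb" additionally draws
    # a per-feature, per-replicate gamma factor (transcript-level biological
    # variability, as in NB models of RNA-seq counts)
    noise: str = "nb"                   # "poisson" | "nb"
    nb_dispersion: float = 0.02
    read_length: int = 50
    n_replicates: int = 2
    # each track is treated as the window of a library with this many mapped
    # reads, so normalization keeps values on the count scale where the +1
    # fold-change prior has its intended damping effect
    library_size: int = 10_000_000
    # ncRNA (exosome-target) decoys
    ncrna_length: int = 150
    ncrna_wt_level: float = 8.0
    ncrna_fold: float = 6.0
    # nucleosome model
    nuc_baseline: float = 0.85
    nfr_depth: float = 0.5
    nfr_sd: float = 40.0
    nfr_center_offset: int = -100       # dip center relative to the TSS
    nuc_noise_sd: float = 0.05
    # misc
    maf_block_cols: int = 10_000
    n_tss_decoys: int = 30

    def __post_init__(self):
        for f in (self.frac_divergent, self.frac_antisense, self.frac_4x,
                  self.frac_3x, self.frac_2x, self.rescue_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        if self.frac_divergent + self.frac_antisense > 1.0:
            raise ValueError("architecture fractions exceed 1")
        if self.frac_4x + self.frac_3x + self.frac_2x > 1.0:
            raise ValueError("conservation fractions exceed 1")
        if self.noise not in ("poisson", "nb"):
            raise ValueError("noise must be 'poisson' or 'nb'")


@dataclass
class _MasterChrom:
    """Alignment truth for one chromosome: master columns with per-strain
    presence and bases."""
    name: str
    n_cols: int
    presence: np.ndarray        # (n_strains, n_cols) bool
    bases: np.ndarray           # (n_strains, n_cols) uint8, 0 where absent

    def strain_cum(self, si: int) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(self.presence[si])))

    def to_strain(self, si: int, m0: int, m1: int) -> tuple[int, int]:
        cum = self.strain_cum(si)
        return int(cum[m0]), int(cum[m1])


@dataclass
class TruthSet:
    config: SimulationConfig
    genomes: dict[str, Genome]
    masters: list[_MasterChrom]
    genes: dict[str, list[Annotation]]           # strain -> transcripts (UTR incl.)
    cds: dict[str, dict[str, Annotation]]        # strain -> gene name -> CDS
    gene_table: pd.DataFrame                     # name, expr, architecture, paired cut
    cuts: pd.DataFrame                           # one row per (cut, strain)
    ncrnas: dict[str, list[Annotation]]
    fragments: pd.DataFrame                      # rescue fragments per (cut, strain)
    maf_blocks: list[MafBlock]
    tracks: dict[tuple[str, str, int], CoverageTrack] = field(default_factory=dict)
    nucleosome: dict[str, CoverageTrack] = field(default_factory=dict)
    tss_clusters: pd.DataFrame | None = None

    def cut_annotations(self, strain: str, present_only: bool = True) -> list[Annotation]:
        rows = self.cuts[self.cuts["strain"] == strain]
        if present_only:
            rows = rows[rows["present"]]
        return [
            Annotation(r.chrom, int(r.start), int(r.end), r.strand, r.name, "CUT",
                       float(r.fold))
            for r in rows.itertuples()
        ]

    def write(self, outdir) -> None:
        """Emit the world as standard-format text files plus a manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"strains": list(self.config.strains), "files": {}}
        write_maf(self.maf_blocks, out / "alignment.maf")
        manifest["files"]["alignment"] = "alignment.maf"
        self.tss_clusters.to_csv(out / "tss_clusters.tsv", sep="\t", index=False)
        manifest["files"]["tss_clusters"] = "tss_clusters.tsv"
        for s in self.config.strains:
            sdir = out / s
            sdir.mkdir(exist_ok=True)
            self.genomes[s].write_fasta(sdir / "genome.fa")
            write_annotations(self.genes[s], sdir / "genes.bed")
            write_annotations(self.cut_annotations(s), sdir / "cuts_truth.bed")
            write_annotations(self.ncrnas[s], sdir / "ncrnas.bed")
            files = {"genome": "genome.fa", "genes": "genes.bed",
                     "cuts_truth": "cuts_truth.bed", "ncrnas": "ncrnas.bed"}
            for (strain, cond, rep), track in self.tracks.items():
                if strain != s:
                    continue
                for strand, tag in (("+", "plus"), ("-", "minus")):
                    name = f"{cond}_rep{rep}_{tag}.bedgraph"
                    track.to_bedgraphs({strand: sdir / name})
                    files[f"{cond}_rep{rep}_{tag}"] = name
            if s in self.nucleosome:
                self.nucleosome[s].to_bedgraphs({".": sdir / "nucleosome.bedgraph"})
                files["nucleosome"] = "nucleosome.bedgraph"
            manifest["files"][s] = files
        self.cuts.to_csv(out / "cuts_truth_table.tsv", sep="\t", index=False)
        manifest["files"]["cuts_table"] = "cuts_truth_table.tsv"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# alignment truth
# ---------------------------------------------------------------------------

def _indel_events(rng, L: int, rate: float, mean_len: float):
    n = rng.poisson(L * rate)
    sites = np.sort(rng.integers(0, L, size=n))
    lengths = rng.geometric(min(1.0, 1.0 / mean_len), size=n)
    return sites, lengths


def _build_master(
    rng: np.random.Generator, name: str, L: int, cfg: SimulationConfig
) -> _MasterChrom:
    n_strains = len(cfg.strains)
    ancestor = rng.choice(_BASES, size=L)
    # insertions: new master columns owned by one strain
    ins = [
        _indel_events(rng, L, cfg.indel_rate / 2.0, cfg.indel_mean_length)
        for _ in range(n_strains)
    ]
    events = sorted(
        (int(site), int(length), si)
        for si, (sites, lengths) in enumerate(ins)
        for site, length in zip(sites, lengths)
    )
    total_ins = sum(e[1] for e in events)
    n_cols = L + total_ins
    presence = np.zeros((n_strains, n_cols), dtype=bool)
    bases = np.zeros((n_strains, n_cols), dtype=np.uint8)
    # map ancestor base i -> master column
    ins_sites = np.array([e[0] for e in events], dtype=np.int64)
    ins_cum = np.concatenate(
        ([0], np.cumsum([e[1] for e in events]))
    ).astype(np.int64)
    anc_cols = np.arange(L) + ins_cum[np.searchsorted(ins_sites, np.arange(L), side="right")]
    presence[:, anc_cols] = True
    for si in range(n_strains):
        row = np.zeros(n_cols, dtype=np.uint8)
        strain_bases = ancestor.copy()
        mut = rng.random(L) < cfg.substitution_rate
        # substitute by rotating within ACGT (guarantees a different base)
        shift = rng.integers(1, 4, size=int(mut.sum()))
        order = np.argsort(_BASES)
        pos_in_alpha = order[np.searchsorted(_BASES[order], strain_bases[mut])]
        strain_bases[mut] = _BASES[(pos_in_alpha + shift) % 4]
        row[anc_cols] = strain_bases
        bases[si] = row
    # insertion columns
    for k, (site, length, si) in enumerate(events):
        col0 = site + ins_cum[k]
        cols = np.arange(col0, col0 + length)
        presence[si, cols] = True
        bases[si, cols] = rng.choice(_BASES, size=length)
    # deletions: drop ancestor-derived columns per strain
    for si in range(n_strains):
        sites, lengths = _indel_events(rng, L, cfg.indel_rate / 2.0, cfg.indel_mean_length)
        for site, length in zip(sites, lengths):
            cols = anc_cols[site : min(site + length, L)]
            presence[si, cols] = False
            bases[si, cols] = 0
    return _MasterChrom(name, n_cols, presence, bases)


def _maf_from_masters(
    masters: Sequence[_MasterChrom], strains: Sequence[str], block_cols: int
) -> list[MafBlock]:
    blocks = []
    for mc in masters:
        sizes = mc.presence.sum(axis=1)
        for c0 in range(0, mc.n_cols, block_cols):
            c1 = min(c0 + block_cols, mc.n_cols)
            blk = MafBlock()
            for si, s in enumerate(strains):
                pres = mc.presence[si, c0:c1]
                if not pres.any():
                    continue
                start = int(mc.presence[si, :c0].sum())
                text_codes = np.where(pres, mc.bases[si, c0:c1], ord("-"))
                blk.seqs.append(
                    MafSeq(
                        strain=s, chrom=mc.name, start=start,
                        size=int(pres.sum()), strand="+",
                        src_size=int(sizes[si]),
                        text=text_codes.astype(np.uint8).tobytes().decode(),
                    )
                )
            if blk.seqs:
                blocks.append(blk)
    return blocks


# ---------------------------------------------------------------------------
# feature planting
# ---------------------------------------------------------------------------

def _cut_length(rng, cfg: SimulationConfig) -> int:
    L = rng.lognormal(np.log(cfg.cut_length_median), cfg.cut_length_sigma)
    return int(np.clip(L, 120, 1500))


def _plan_units(rng, cfg: SimulationConfig):
    """Assign architectures and conservation patterns, returning shuffled
    placement units.  Each unit is a dict of local-coordinate features."""
    n_div = int(round(cfg.frac_divergent * cfg.n_cuts))
    n_anti = int(round(cfg.frac_antisense * cfg.n_cuts))
    n_free = cfg.n_cuts - n_div - n_anti
    archs = ["divergent"] * n_div + ["antisense"] * n_anti + ["free"] * n_free
    rng.shuffle(archs)
    n4 = int(round(cfg.frac_4x * cfg.n_cuts))
    n3 = int(round(cfg.frac_3x * cfg.n_cuts))
    n2 = int(round(cfg.frac_2x * cfg.n_cuts))
    classes = ["4x"] * n4 + ["3x"] * n3 + ["2x"] * n2 + ["unique"] * (
        cfg.n_cuts - n4 - n3 - n2
    )
    rng.shuffle(classes)
    if n_div + n_anti > cfg.n_genes:
        raise ValueError("more paired CUTs requested than genes available")
    units = []
    gi = 0
    ci = 0
    for arch in archs:
        if arch in ("divergent", "antisense"):
            units.append({"type": "gene", "arch": arch, "cut_class": classes[ci]})
            ci += 1
            gi += 1
        else:
            units.append({"type": "cut", "arch": "free", "cut_class": classes[ci]})
            ci += 1
    for _ in range(cfg.n_genes - gi):
        units.append({"type": "gene", "arch": None, "cut_class": None})
    for _ in range(cfg.n_ncrnas):
        units.append({"type": "ncrna"})
    rng.shuffle(units)
    return units


MIN_ELEVATED_GAP = 650   # keep successive rrp6-elevated features apart so
                         # their decoded segments cannot bridge via the
                         # 450-bp merge rule even after boundary scatter


def _place_world(rng, cfg: SimulationConfig, masters: Sequence[_MasterChrom]):
    """Lay out units sequentially in master coordinates."""
    units = _plan_units(rng, cfg)
    per_chrom = np.array_split(np.arange(len(units)), cfg.n_chroms)
    genes, cuts, ncrnas = [], [], []
    g_idx = c_idx = n_idx = 0
    for mc, unit_ids in zip(masters, per_chrom):
        pos = 300
        last_elev_end = -MIN_ELEVATED_GAP
        for uid in unit_ids:
            u = units[uid]
            flip = rng.random() < 0.5
            if u["type"] == "ncrna":
                pos = max(pos, last_elev_end + MIN_ELEVATED_GAP)
                start, end = pos, pos + cfg.ncrna_length
                last_elev_end = end
                ncrnas.append(
                    {"name": f"snoRNA_{n_idx+1:03d}", "chrom": mc.name,
                     "m_start": start, "m_end": end,
                     "strand": "-" if flip else "+"}
                )
                n_idx += 1
                pos = end + int(rng.integers(350, 550))
            elif u["type"] == "cut":
                L = _cut_length(rng, cfg)
                pos = max(pos, last_elev_end + MIN_ELEVATED_GAP)
                start, end = pos, pos + L
                last_elev_end = end
                cuts.append(
                    {"name": f"cut_{c_idx+1:03d}", "chrom": mc.name,
                     "m_start": start, "m_end": end,
                     "strand": "-" if flip else "+",
                     "architecture": "free", "presence_class": u["cut_class"],
                     "paired_gene": ""}
                )
                c_idx += 1
                pos = end + int(rng.integers(500, 700))
            else:  # gene unit, possibly with a paired CUT
                u5 = int(rng.integers(50, 150))
                cds_len = int(rng.integers(800, 1600))
                u3 = int(rng.integers(50, 150))
                tlen = u5 + cds_len + u3
                arch = u["arch"]
                cut_local = None
                if arch == "divergent":
                    L = _cut_length(rng, cfg)
                    # shared-NFR5 overlap equals the TSS separation d, so the
                    # >= 100 bp / >= 50% sharing rule needs d >= ~100 + jitter
                    d = int(rng.integers(130, 190))
                    cut_local = (-d - L, -d)
                    lead = d + L
                elif arch == "antisense":
                    L = min(_cut_length(rng, cfg), tlen - 120)
                    e = int(rng.integers(30, 90))
                    cut_local = (tlen - e - L, tlen - e)
                    lead = 0
                else:
                    lead = 0
                # `lead` is the room the paired CUT needs on the gene's
                # upstream side, which mirroring moves to the other side
                g_start = pos + (0 if flip else lead)
                g_end = g_start + tlen
                if cut_local is not None:
                    # keep this unit's elevated CUT clear of the previous one
                    a, b = cut_local
                    elev_start = (g_start + (tlen - b)) if flip else (g_start + a)
                    deficit = (last_elev_end + MIN_ELEVATED_GAP) - elev_start
                    if deficit > 0:
                        g_start += deficit
                        g_end += deficit
                gname = f"gene_{g_idx+1:03d}"
                if flip:
                    strand = "-"
                    cds = (g_start + u3, g_end - u5)
                else:
                    strand = "+"
                    cds = (g_start + u5, g_end - u3)
                genes.append(
                    {"name": gname, "chrom": mc.name, "m_start": g_start,
                     "m_end": g_end, "strand": strand,
                     "cds_start": cds[0], "cds_end": cds[1],
                     "architecture": arch or "none"}
                )
                if cut_local is not None:
                    a, b = cut_local
                    if flip:
                        cs, ce = g_start + (tlen - b), g_start + (tlen - a)
                        cstrand = "+"
                    else:
                        cs, ce = g_start + a, g_start + b
                        cstrand = "-"
                    last_elev_end = ce
                    cuts.append(
                        {"name": f"cut_{c_idx+1:03d}", "chrom": mc.name,
                         "m_start": cs, "m_end": ce, "strand": cstrand,
                         "architecture": arch, "presence_class": u["cut_class"],
                         "paired_gene": gname}
                    )
                    c_idx += 1
                g_idx += 1
                pos = g_end + (lead if flip else 0) + int(rng.integers(350, 550))
        if pos > mc.n_cols - 300:
            raise ValueError(
                f"infeasible placement: needed {pos} master columns on "
                f"{mc.name} of {mc.n_cols}"
            )
    return genes, cuts, ncrnas


# ---------------------------------------------------------------------------
# world assembly
# ---------------------------------------------------------------------------

def simulate_world(config: SimulationConfig | None = None, eager_tracks: bool = True) -> TruthSet:
    """Build a fully reproducible synthetic world from ``config.seed``."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n_strains = len(cfg.strains)
    masters = [
        _build_master(rng, f"chr{i+1}", cfg.chrom_length, cfg)
        for i in range(cfg.n_chroms)
    ]
    mc_by_name = {mc.name: mc for mc in masters}
    gene_rows, cut_rows, ncrna_rows = _place_world(rng, cfg, masters)

    # strain genomes
    genomes = {}
    for si, s in enumerate(cfg.strains):
        sizes, seqs = {}, {}
        for mc in masters:
            pres = mc.presence[si]
            seq = mc.bases[si][pres].tobytes().decode()
            sizes[mc.name] = len(seq)
            seqs[mc.name] = seq
        genomes[s] = Genome(sizes, seqs)

    # expression levels and architecture effects
    gene_expr = {}
    for g in gene_rows:
        e = rng.lognormal(np.log(cfg.gene_expr_mean), cfg.gene_expr_sigma)
        if g["architecture"] == "divergent":
            e *= 2.0 ** cfg.divergent_shift_log2
        gene_expr[g["name"]] = e
    cut_folds = {
        c["name"]: float(rng.uniform(*cfg.cut_fold_range)) for c in cut_rows
    }
    cut_wt = {
        c["name"]: float(rng.lognormal(np.log(cfg.cut_wt_level), 0.3))
        for c in cut_rows
    }

    # conservation: which strains carry each CUT; rescue fragments
    presence_map: dict[str, np.ndarray] = {}
    rescue_strain: dict[str, int] = {}
    for c in cut_rows:
        cls = c["presence_class"]
        k = {"4x": n_strains, "3x": n_strains - 1, "2x": 2, "unique": 1}[cls]
        present = np.zeros(n_strains, dtype=bool)
        present[rng.choice(n_strains, size=k, replace=False)] = True
        presence_map[c["name"]] = present
        if cls == "3x" and rng.random() < cfg.rescue_fraction:
            rescue_strain[c["name"]] = int(np.flatnonzero(~present)[0])

    # project features to strain coordinates (CUTs jittered per strain)
    strain_idx = {s: i for i, s in enumerate(cfg.strains)}
    genes: dict[str, list[Annotation]] = {s: [] for s in cfg.strains}
    cds: dict[str, dict[str, Annotation]] = {s: {} for s in cfg.strains}
    ncrnas: dict[str, list[Annotation]] = {s: [] for s in cfg.strains}
    cut_records = []
    frag_records = []
    cums = {
        (s, mc.name): mc.strain_cum(strain_idx[s])
        for s in cfg.strains for mc in masters
    }
    for si, s in enumerate(cfg.strains):
        for g in gene_rows:
            cum = cums[(s, g["chrom"])]
            a, b = int(cum[g["m_start"]]), int(cum[g["m_end"]])
            if b - a < 100:
                continue
            genes[s].append(
                Annotation(g["chrom"], a, b, g["strand"], g["name"], "gene",
                           gene_expr[g["name"]])
            )
            ca, cb = int(cum[g["cds_start"]]), int(cum[g["cds_end"]])
            if cb > ca:
                cds[s][g["name"]] = Annotation(
                    g["chrom"], ca, cb, g["strand"], g["name"], "CDS"
                )
        for nc in ncrna_rows:
            cum = cums[(s, nc["chrom"])]
            a, b = int(cum[nc["m_start"]]), int(cum[nc["m_end"]])
            if b - a >= 50:
                ncrnas[s].append(
                    Annotation(nc["chrom"], a, b, nc["strand"], nc["name"], "snoRNA")
                )
        for c in cut_rows:
            cum = cums[(s, c["chrom"])]
            a, b = int(cum[c["m_start"]]), int(cum[c["m_end"]])
            present = bool(presence_map[c["name"]][si])
            jitter = rng.normal(0, cfg.jitter_sd, size=2) if present else (0.0, 0.0)
            a2 = max(0, int(round(a + jitter[0])))
            b2 = min(int(cum[-1]), int(round(b + jitter[1])))
            if b2 - a2 < 60:
                a2, b2 = a, b
            cut_records.append(
                {"name": c["name"], "strain": s, "chrom": c["chrom"],
                 "start": a2, "end": b2, "strand": c["strand"],
                 "fold": cut_folds[c["name"]], "wt_level": cut_wt[c["name"]],
                 "architecture": c["architecture"],
                 "presence_class": c["presence_class"],
                 "paired_gene": c["paired_gene"], "present": present}
            )
            if rescue_strain.get(c["name"]) == si:
                mid = (a + b) // 2
                half = int(rng.integers(15, 23))
                frag_records.append(
                    {"name": c["name"] + "_frag", "cut": c["name"], "strain": s,
                     "chrom": c["chrom"], "start": mid - half, "end": mid + half,
                     "strand": c["strand"], "fold": cut_folds[c["name"]],
                     "wt_level": cut_wt[c["name"]]}
                )

    gene_table = pd.DataFrame(
        [{"name": g["name"], "chrom": g["chrom"], "strand": g["strand"],
          "expr": gene_expr[g["name"]], "architecture": g["architecture"]}
         for g in gene_rows]
    )
    truth = TruthSet(
        config=cfg,
        genomes=genomes,
        masters=masters,
        genes=genes,
        cds=cds,
        gene_table=gene_table,
        cuts=pd.DataFrame(cut_records),
        ncrnas=ncrnas,
        fragments=pd.DataFrame(frag_records),
        maf_blocks=_maf_from_masters(masters, cfg.strains, cfg.maf_block_cols),
    )
    truth.tss_clusters = _tss_clusters(rng, truth)
    if eager_tracks:
        for si, s in enumerate(cfg.strains):
            for cond in ("WT", "rrp6"):
                for rep in range(1, cfg.n_replicates + 1):
                    truth.tracks[(s, cond, rep)] = simulate_coverage(truth, s, cond, rep)
            truth.nucleosome[s] = simulate_nucleosome(truth, s)
        s0 = cfg.strains[0]
        truth.tracks[(s0, "nascent", 1)] = simulate_coverage(truth, s0, "nascent", 1)
    return truth


def _expected_lambda(
    truth: TruthSet, strain: str, condition: str,
    rng: np.random.Generator | None = None,
) -> CoverageTrack:
    """Expected per-base coverage for one strain and condition.

    When ``rng`` is given and the config noise model is "nb", each feature's
    level is scaled by a gamma factor (mean 1, variance = dispersion),
    modelling transcript-level biological variability between replicates.
    """
    cfg = truth.config

    def jitter() -> float:
        if rng is None or cfg.noise != "nb" or cfg.nb_dispersion <= 0:
            return 1.0
        shape = 1.0 / cfg.nb_dispersion
        return float(rng.gamma(shape, 1.0 / shape))

    lam = CoverageTrack.zeros(truth.genomes[strain])
    for k in lam.data:
        lam.data[k] += cfg.baseline
    arch_by_gene = dict(zip(truth.gene_table["name"], truth.gene_table["architecture"]))
    for g in truth.genes[strain]:
        e = g.score * jitter()
        arch = arch_by_gene[g.name]
        if arch == "antisense" and condition in ("WT", "rrp6"):
            e = e * cfg.antisense_reduction
        lam.data[(g.chrom, g.strand)][g.start : g.end] += e
    rows = truth.cuts[(truth.cuts["strain"] == strain) & truth.cuts["present"]]
    for r in rows.itertuples():
        if condition == "WT":
            level = r.wt_level
        else:  # rrp6 and nascent both see stabilized/active CUT transcription
            level = r.wt_level * r.fold
        lam.data[(r.chrom, r.strand)][int(r.start) : int(r.end)] += level * jitter()
    frows = truth.fragments[truth.fragments["strain"] == strain] if len(
        truth.fragments
    ) else truth.fragments
    for r in (frows.itertuples() if len(frows) else ()):
        level = r.wt_level if condition == "WT" else r.wt_level * r.fold
        lam.data[(r.chrom, r.strand)][int(r.start) : int(r.end)] += level * jitter()
    for nc in truth.ncrnas[strain]:
        level = cfg.ncrna_wt_level
        if condition in ("rrp6", "nascent"):
            level *= cfg.ncrna_fold
        lam.data[(nc.chrom, nc.strand)][nc.start : nc.end] += level * jitter()
    return lam


def simulate_coverage(
    truth: TruthSet, strain: str, condition: str, replicate: int = 1,
    seed: int | None = None,
) -> CoverageTrack:
    """Raw (unnormalized) coverage with read-length-correlated counting noise.

    Reads are simulated as per-base start counts (Poisson, or gamma-Poisson
    for negative-binomial overdispersion) extended by the read length, so
    neighbouring positions share noise as they would from real reads.
    """
    cfg = truth.config
    cond_idx = {"WT": 0, "rrp6": 1, "nascent": 2}[condition]
    si = list(cfg.strains).index(strain)
    if seed is None:
        seed_seq = [cfg.seed, 7919, si, cond_idx, replicate]
    else:
        seed_seq = [seed]
    rng = np.random.default_rng(seed_seq)
    lam = _expected_lambda(truth, strain, condition, rng=rng)
    track = CoverageTrack.zeros(truth.genomes[strain])
    Lr = cfg.read_length
    total_reads = 0
    for k, arr in lam.data.items():
        rate = arr / Lr
        starts = rng.poisson(rate)
        total_reads += int(starts.sum())
        cs = np.concatenate(([0], np.cumsum(starts)))
        idx = np.arange(arr.size)
        if k[1] == "-":
            # minus-strand reads extend upstream (leftward in genome coords)
            cov = cs[np.minimum(idx + Lr, arr.size)] - cs[idx]
        else:
            cov = cs[idx + 1] - cs[np.maximum(idx + 1 - Lr, 0)]
        track.data[k] = cov.astype(float)
    # the simulated window is a slice of a larger library; the read count
    # used for normalization is the library size, not the in-window count
    track.mapped_read_count = int(cfg.library_size) if cfg.library_size else max(
        total_reads, 1
    )
    return track


def simulate_nucleosome(truth: TruthSet, strain: str) -> CoverageTrack:
    """Unstranded nucleosome occupancy: baseline with Gaussian NFR dips at
    gene TSS/TTS and CUT TSS positions; none at CUT 3' ends."""
    cfg = truth.config
    si = list(cfg.strains).index(strain)
    rng = np.random.default_rng([cfg.seed, 104729, si])
    genome = truth.genomes[strain]
    track = CoverageTrack.zeros(genome, strands=(".",))

    def dip(depletion, center):
        # overlapping NFRs (e.g. a shared divergent promoter) form one
        # depleted region: depletion fields combine by maximum, not by sum
        w = int(4 * cfg.nfr_sd)
        x = np.arange(max(0, center - w), min(depletion.size, center + w))
        np.maximum.at(
            depletion, x,
            cfg.nfr_depth * np.exp(-0.5 * ((x - center) / cfg.nfr_sd) ** 2),
        )

    for chrom, size in genome.chrom_sizes.items():
        depletion = np.zeros(size)
        for g in truth.genes[strain]:
            if g.chrom != chrom:
                continue
            tss = g.start if g.strand == "+" else g.end - 1
            tts = g.end - 1 if g.strand == "+" else g.start
            sign = 1 if g.strand == "+" else -1
            dip(depletion, tss + sign * cfg.nfr_center_offset)
            dip(depletion, tts)
        rows = truth.cuts[
            (truth.cuts["strain"] == strain) & truth.cuts["present"]
            & (truth.cuts["chrom"] == chrom)
        ]
        for r in rows.itertuples():
            tss = int(r.start) if r.strand == "+" else int(r.end) - 1
            sign = 1 if r.strand == "+" else -1
            dip(depletion, tss + sign * cfg.nfr_center_offset)
        arr = (
            np.full(size, cfg.nuc_baseline)
            + rng.normal(0, cfg.nuc_noise_sd, size=size)
            - depletion
        )
        track.data[(chrom, ".")] = np.clip(arr, 0.01, None)
    return track


def _tss_clusters(rng, truth: TruthSet) -> pd.DataFrame:
    """TSS cluster table for the first strain: one cluster near each planted
    CUT TSS plus low-fold decoys, with A/B/I categories."""
    cfg = truth.config
    s0 = cfg.strains[0]
    rows = []
    present = truth.cuts[(truth.cuts["strain"] == s0) & truth.cuts["present"]]
    for r in present.itertuples():
        tss = int(r.start) if r.strand == "+" else int(r.end) - 1
        pos = tss + int(round(rng.normal(0, 10)))
        rows.append(
            {"chrom": r.chrom, "pos": max(0, pos), "strand": r.strand,
             "category": rng.choice(["A", "B", "I"]),
             "fold": float(max(1.5, r.fold * rng.lognormal(0, 0.1)))}
        )
    chroms = list(truth.genomes[s0].chrom_sizes)
    for _ in range(cfg.n_tss_decoys):
        chrom = rng.choice(chroms)
        rows.append(
            {"chrom": chrom,
             "pos": int(rng.integers(0, truth.genomes[s0].chrom_sizes[chrom])),
             "strand": rng.choice(["+", "-"]),
             "category": rng.choice(["A", "B", "I", "C"]),
             "fold": float(rng.uniform(0.5, 1.4))}
        )
    return pd.DataFrame(rows)


def simulate_alignment(truth: TruthSet) -> list[MafBlock]:
    """The world's MAF blocks (already derived from the master alignment)."""
    return truth.maf_blocks
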