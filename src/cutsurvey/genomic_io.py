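"""Readers and writers for the standard genomic formats used throughout the package.

All coordinates are internally 0-based half-open (BED convention); GFF3's
1-based inclusive coordinates are converted at the boundary.  Strand-specific
signal is kept as two dense per-chromosome arrays; unstranded signal (e.g.
nucleosome occupancy) uses the single pseudo-strand ``"."``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

STRANDS = ("+", "-")
UNSTRANDED = (".",)


@dataclass(frozen=True, order=True)
class Annotation:
    """A stranded genomic interval: the universal currency of CUTs, genes,
    ncRNAs and NFRs.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``length >= 1``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    feature_class: str = ""
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Annotation") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def with_(self, **kw) -> "Annotation":
        return replace(self, **kw)


@dataclass
class Genome:
    """Chromosome sizes and (optionally) sequences."""

    chrom_sizes: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self):
        for c, n in self.chrom_sizes.items():
            if n < 1:
                raise ValueError(f"chromosome {c} has non-positive length {n}")
        if self.sequences is not None:
            for c, s in self.sequences.items():
                if len(s) != self.chrom_sizes[c]:
                    raise ValueError(
                        f"sequence length {len(s)} != declared size "
                        f"{self.chrom_sizes[c]} for {c}"
                    )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def check_interval(self, ann: Annotation) -> None:
        if ann.chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {ann.chrom!r}")
        if ann.end > self.chrom_sizes[ann.chrom]:
            raise ValueError(
                f"interval {ann.chrom}:{ann.start}-{ann.end} exceeds "
                f"chromosome size {self.chrom_sizes[ann.chrom]}"
            )

    @classmethod
    def from_sizes_file(cls, path) -> "Genome":
        sizes = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
        return cls(sizes)

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls({c: len(s) for c, s in seqs.items()}, seqs)

    def write_fasta(self, path, width: int = 80) -> None:
        if self.sequences is None:
            raise ValueError("genome carries no sequences")
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations (BED / GFF3)
# ---------------------------------------------------------------------------

def _sorted(anns: Iterable[Annotation]) -> list[Annotation]:
    return sorted(anns, key=lambda a: (a.chrom, a.start, a.end, a.strand, a.name))


def read_annotations(path, format: str = "BED") -> list[Annotation]:
    """Read a BED6(+1) or GFF3 file into sorted :class:`Annotation` records.

    BED coordinates pass through unchanged; GFF3 start is shifted by -1.
    An optional 7th BED column carries the feature class.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unknown annotation format {format!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if fmt == "BED":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else ""
                    score = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else None
                    strand = fields[5] if len(fields) > 5 else "+"
                    fclass = fields[6] if len(fields) > 6 else ""
                else:
                    chrom = fields[0]
                    fclass = fields[2]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    score = float(fields[5]) if fields[5] not in (".", "") else None
                    strand = fields[6]
                    name = ""
                    for kv in fields[8].rstrip(";").split(";"):
                        if "=" in kv:
                            k, v = kv.split("=", 1)
                            if k.strip() in ("ID", "Name"):
                                name = v.strip()
                                break
                ann = Annotation(chrom, start, end, strand, name, fclass, score)
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed {fmt} line {lineno}: {exc}") from exc
            out.append(ann)
    return _sorted(out)


def write_annotations(annotations: Sequence[Annotation], path, format: str = "BED") -> None:
    """Write annotations; ``read_annotations(write_annotations(x)) == sorted(x)``."""
    fmt = format.upper()
    anns = _sorted(annotations)
    with open(path, "w") as fh:
        if fmt == "BED":
            has_class = any(a.feature_class for a in anns)
            for a in anns:
                score = "0" if a.score is None else f"{a.score:g}"
                cols = [a.chrom, str(a.start), str(a.end), a.name or ".", score, a.strand]
                if has_class:
                    cols.append(a.feature_class or ".")
                fh.write("\t".join(cols) + "\n")
        elif fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for a in anns:
                score = "." if a.score is None else f"{a.score:g}"
                fh.write(
                    "\t".join(
                        [
                            a.chrom,
                            "cutsurvey",
                            a.feature_class or "region",
                            str(a.start + 1),
                            str(a.end),
                            score,
                            a.strand,
                            ".",
                            f"ID={a.name}" if a.name else ".",
                        ]
                    )
                    + "\n"
                )
        else:
            raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# dense signal tracks (bedGraph / wiggle)
# ---------------------------------------------------------------------------

def _parse_bedgraph(lines, genome: Genome, arrays) -> None:
    covered = {c: np.zeros(n, dtype=bool) for c, n in genome.chrom_sizes.items()}
    for lineno, line in lines:
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"malformed bedGraph line {lineno}: {line!r}")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if chrom not in genome.chrom_sizes:
            raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
        if start < 0 or end > genome.chrom_sizes[chrom] or start >= end:
            raise ValueError(
                f"line {lineno}: interval {start}-{end} outside {chrom} "
                f"(size {genome.chrom_sizes[chrom]})"
            )
        if covered[chrom][start:end].any():
            raise ValueError(f"line {lineno}: overlapping bedGraph intervals on {chrom}")
        covered[chrom][start:end] = True
        arrays[chrom][start:end] = value


def _parse_wiggle(lines, genome: Genome, arrays) -> None:
    chrom, pos, step, span, mode = None, 0, 1, 1, None
    for lineno, line in lines:
        if line.startswith("fixedStep") or line.startswith("variableStep"):
            kv = dict(f.split("=") for f in line.split()[1:])
            chrom = kv["chrom"]
            if chrom not in genome.chrom_sizes:
                raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
            span = int(kv.get("span", 1))
            mode = line.split()[0]
            if mode == "fixedStep":
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
            continue
        if mode is None:
            raise ValueError(f"line {lineno}: wiggle data before a step header")
        fields = line.split()
        if mode == "variableStep":
            start = int(fields[0]) - 1
            value = float(fields[1])
        else:
            start = pos
            value = float(fields[0])
            pos += step
        if start < 0 or start + span > genome.chrom_sizes[chrom]:
            raise ValueError(f"line {lineno}: position outside {chrom}")
        arrays[chrom][start : start + span] = value


def read_dense(path, genome: Genome, format: str | None = None) -> dict[str, np.ndarray]:
    """Read a bedGraph or wiggle file into dense per-chromosome arrays
    (0 where uncovered).  Format is sniffed from content when not given."""
    text = Path(path).read_text()
    lines = [
        (i, ln)
        for i, ln in enumerate(text.splitlines(), 1)
        if ln.strip() and not ln.startswith(("#", "track", "browser"))
    ]
    if format is None:
        is_wig = any(
            ln.startswith(("fixedStep", "variableStep")) for _, ln in lines
        )
        format = "wiggle" if is_wig else "bedGraph"
    arrays = {c: np.zeros(n) for c, n in genome.chrom_sizes.items()}
    if format == "bedGraph":
        _parse_bedgraph(lines, genome, arrays)
    elif format == "wiggle":
        _parse_wiggle(lines, genome, arrays)
    else:
        raise ValueError(f"unknown track format {format!r}")
    return arrays


def write_dense(arrays: Mapping[str, np.ndarray], path) -> None:
    """Write dense arrays as bedGraph, run-length compressing equal values
    and omitting zero runs."""
    with open(path, "w") as fh:
        for chrom in arrays:
            vals = np.asarray(arrays[chrom], dtype=float)
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")


# ---------------------------------------------------------------------------
# MAF multiple alignments
# ---------------------------------------------------------------------------

@dataclass
class MafSeq:
    strain: str
    chrom: str
    start: int       # 0-based on `strand`
    size: int        # number of non-gap bases
    strand: str
    src_size: int
    text: str        # aligned text with '-'


@dataclass
class MafBlock:
    seqs: list[MafSeq] = field(default_factory=list)

    @property
    def ncols(self) -> int:
        return len(self.seqs[0].text) if self.seqs else 0

    def strain(self, name: str) -> MafSeq | None:
        for s in self.seqs:
            if s.strain == name:
                return s
        return None


def read_maf(path, strains: Sequence[str] | None = None) -> list[MafBlock]:
    """Parse a MAF file, keeping rows whose source is ``strain.chrom`` for
    the named strains (all strains when ``strains`` is None).  Raises on
    ragged blocks (unequal aligned lengths)."""
    blocks = []
    for msa in AlignIO.parse(str(path), "maf"):
        blk = MafBlock()
        ncols = None
        for rec in msa:
            src = rec.id
            strain, _, chrom = src.partition(".")
            if strains is not None and strain not in strains:
                continue
            text = str(rec.seq)
            if ncols is None:
                ncols = len(text)
            elif len(text) != ncols:
                raise ValueError(f"ragged MAF block: {src} has {len(text)} columns, expected {ncols}")
            ann = rec.annotations
            size = ann["size"]
            if len(text) - text.count("-") != size:
                raise ValueError(f"MAF row {src}: declared size {size} != non-gap bases")
            blk.seqs.append(
                MafSeq(
                    strain=strain,
                    chrom=chrom,
                    start=int(ann["start"]),
                    size=int(size),
                    strand="+" if ann["strand"] in (1, "+") else "-",
                    src_size=int(ann["srcSize"]),
                    text=text,
                )
            )
        if blk.seqs:
            blocks.append(blk)
    return blocks


def write_maf(blocks: Sequence[MafBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for blk in blocks:
            fh.write("a\n")
            for s in blk.seqs:
                fh.write(
                    f"s {s.strain}.{s.chrom} {s.start} {s.size} {s.strand} "
                    f"{s.src_size} {s.text}\n"
                )
            fh.write("\n")
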