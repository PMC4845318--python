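"""End-to-end convenience drivers: tracks -> fold change -> HMM -> refined
CUTs, per strain and across a multi-strain world, plus recovery evaluation
against a synthetic truth set."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import conservation as cons
from .coverage import CoverageTrack, FoldChangeTrack, fold_change_pipeline
from .edhmm import Discretizer, ExpandedHMM, build_model, decode, segments_from_path
from .genomic_io import Annotation
from .refine import RefinedSet, RefinementConfig, refine
from .simulate import TruthSet


@dataclass
class StrainResult:
    strain: str
    fc: FoldChangeTrack
    rrp6_avg: CoverageTrack
    wt_avg: CoverageTrack
    raw: list[Annotation]
    refined: RefinedSet

    @property
    def final(self) -> list[Annotation]:
        return self.refined.final


def call_cuts(
    wt_reps: Sequence[CoverageTrack],
    rrp6_reps: Sequence[CoverageTrack],
    exclusions: Sequence[Annotation] = (),
    model: ExpandedHMM | None = None,
    discretizer: Discretizer | None = None,
    refinement: RefinementConfig | None = None,
    strain: str = "",
) -> StrainResult:
    """The full single-strain pipeline on raw replicate coverage tracks."""
    model = model or build_model()
    discretizer = discretizer or Discretizer()
    refinement = refinement or RefinementConfig()
    fc, rrp6_avg, wt_avg = fold_change_pipeline(wt_reps, rrp6_reps)
    paths = decode(fc, model, discretizer)
    raw = segments_from_path(paths)
    refined = refine(raw, refinement, rrp6_avg, exclusions)
    return StrainResult(strain, fc, rrp6_avg, wt_avg, raw, refined)


def run_world(
    truth: TruthSet,
    model: ExpandedHMM | None = None,
    discretizer: Discretizer | None = None,
    refinement: RefinementConfig | None = None,
) -> dict[str, StrainResult]:
    """Run the calling pipeline on every strain of a synthetic world."""
    out = {}
    for s in truth.config.strains:
        wt = [truth.tracks[(s, "WT", r)] for r in range(1, truth.config.n_replicates + 1)]
        rr = [truth.tracks[(s, "rrp6", r)] for r in range(1, truth.config.n_replicates + 1)]
        out[s] = call_cuts(
            wt, rr, exclusions=truth.ncrnas[s], model=model,
            discretizer=discretizer, refinement=refinement, strain=s,
        )
    return out


def conservation_analysis(
    truth: TruthSet,
    results: Mapping[str, StrainResult],
    max_gap_fraction: float = 0.25,
    fourx_threshold: float = 3.5,
) -> tuple[list[cons.ConservationRegion], dict[tuple[str, str], str], cons.AlignmentMap]:
    """Project per-strain calls through the world's alignment and classify
    conserved expression; returns (regions, per-CUT classes, alignment map)."""
    amap = cons.build_map(truth.maf_blocks, list(truth.config.strains))
    projected, rescue = {}, {}
    for s, res in results.items():
        projected[s], _ = cons.project(res.final, amap, s, max_gap_fraction)
        rescue[s], _ = cons.project(
            res.refined.removed_raw, amap, s, max_gap_fraction=1.0
        )
    regions = cons.conservation_call(projected, rescue, fourx_threshold)
    classes = cons.classify_cuts(regions, projected)
    return regions, classes, amap


def _reciprocal_match(a: Annotation, b: Annotation, min_frac: float) -> bool:
    ov = a.overlap_bp(b)
    return (
        a.strand == b.strand
        and ov >= min_frac * a.length
        and ov >= min_frac * b.length
    )


@dataclass
class RecoveryReport:
    strain: str
    n_eligible: int
    n_recovered: int
    n_calls: int
    n_false: int

    @property
    def recovery(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else float("nan")

    @property
    def fdr(self) -> float:
        return self.n_false / self.n_calls if self.n_calls else 0.0


def evaluate_recovery(
    truth: TruthSet,
    result: StrainResult,
    min_fold: float = 2.0,
    min_length: int = 200,
    min_recip: float = 0.5,
) -> RecoveryReport:
    """Score final calls against planted CUTs at >= ``min_recip`` reciprocal
    overlap.  Eligible plants: present in the strain, fold >= min_fold and
    planted length >= min_length.  A call matching no planted CUT (of any
    fold or length) is a false discovery."""
    s = result.strain
    rows = truth.cuts[(truth.cuts["strain"] == s) & truth.cuts["present"]]
    planted = [
        Annotation(r.chrom, int(r.start), int(r.end), r.strand, r.name, "CUT")
        for r in rows.itertuples()
    ]
    eligible = [
        Annotation(r.chrom, int(r.start), int(r.end), r.strand, r.name, "CUT")
        for r in rows.itertuples()
        if r.fold >= min_fold and (int(r.end) - int(r.start)) >= min_length
    ]
    calls = result.final
    n_recovered = sum(
        any(_reciprocal_match(p, c, min_recip) for c in calls) for p in eligible
    )
    n_false = sum(
        not any(_reciprocal_match(c, p, min_recip) for p in planted) for c in calls
    )
    return RecoveryReport(
        strain=s,
        n_eligible=len(eligible),
        n_recovered=int(n_recovered),
        n_calls=len(calls),
        n_false=int(n_false),
    )


def conservation_accuracy(
    truth: TruthSet,
    results: Mapping[str, StrainResult],
    classes: Mapping[tuple[str, str], str],
    presence_class: str = "4x",
    min_recip: float = 0.5,
) -> float:
    """Fraction of planted CUTs of the given conservation pattern assigned
    the correct class.  Each plant is linked to final calls by reciprocal
    overlap in every strain where it was planted; the best class among its
    matched calls is compared with the plant's true pattern."""
    rank = {"unique": 1, "2x": 2, "3x": 3, "4x": 4}
    plants = truth.cuts[
        (truth.cuts["presence_class"] == presence_class) & truth.cuts["present"]
    ]
    n_ok = 0
    n_scored = 0
    for name, group in plants.groupby("name"):
        assigned = []
        for r in group.itertuples():
            truth_ann = Annotation(r.chrom, int(r.start), int(r.end), r.strand, r.name)
            for call in results[r.strain].final:
                if _reciprocal_match(truth_ann, call, min_recip):
                    cls = classes.get((r.strain, call.name))
                    if cls is not None:
                        assigned.append(cls)
        if assigned:
            n_scored += 1
            best = max(assigned, key=lambda c: rank.get(c, 0))
            if best == presence_class:
                n_ok += 1
    if n_scored == 0:
        return float("nan")
    return n_ok / n_scored
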