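"""Donor-plasmid backbone screening and long-read allele assignment.

Two detectors for the unintended plasmid integration:

* a short-read screen computing per-base depth over the plasmid *backbone*
  (the vector sequence with the HDR-template insert masked out, so genome
  homology cannot inflate coverage); an animal is called backbone-positive
  when the covered fraction (breadth) reaches a threshold;
* a long-read assay assigning noisy reads to the clean Celtic allele (Pc)
  versus the plasmid-integrated allele (Pc*) by aligning each baited read to
  both allele models and requiring a diagnostic score margin at sequence
  that differs between the models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._align import (
    DEFAULT_SCORING,
    Scoring,
    align_edlib,
    align_local,
    best_strand_alignment,
    reverse_complement,
)
from .bait_classify import BaitIndex, SequencingRead, build_bait_index
from .locus_models import AlleleModel, NucSequence, diff_interval


@dataclass
class BackboneScreenResult:
    sample_id: str
    breadth: float
    mean_depth: float
    present: bool
    threshold: float

    def __post_init__(self):
        if not (0.0 <= self.breadth <= 1.0):
            raise ValueError("breadth must lie in [0, 1]")


def mask_hdr_insert(plasmid: NucSequence, hdr_template: NucSequence) -> NucSequence:
    """Remove the HDR-template insert from the plasmid, leaving backbone only.

    The insert is located by alignment of the template to the plasmid.
    """
    aln = align_edlib(hdr_template.bases, plasmid.bases)
    if aln is None or aln.edit_distance > 0.2 * len(hdr_template):
        raise ValueError("HDR template does not align inside the plasmid sequence")
    backbone = plasmid.bases[: aln.target_start] + plasmid.bases[aln.target_end :]
    return NucSequence(f"{plasmid.id}_backbone", backbone)


def screen_backbone(
    reads: Iterable[SequencingRead],
    backbone_only: NucSequence,
    breadth_threshold: float = 0.25,
    sample_id: str = "sample",
    scoring: Scoring = DEFAULT_SCORING,
    bait_k: int = 25,
    min_anchor: int = 30,
    min_identity: float = 0.9,
) -> BackboneScreenResult:
    """Per-base backbone depth from best local read alignments.

    Reads are prefiltered by a backbone k-mer bait; surviving reads are
    locally aligned on both strands and their aligned target span counted
    when at least ``min_anchor`` bases align at ``min_identity``.
    """
    backbone = backbone_only.bases
    index = build_bait_index([backbone_only], k=bait_k)
    depth = np.zeros(len(backbone), dtype=np.int32)
    n_reads = 0
    for read in reads:
        n_reads += 1
        if index.count_hits(read.bases, stop_at=1) < 1:
            continue
        best = None
        for seq in (read.bases, reverse_complement(read.bases)):
            aln = align_local(seq, backbone, scoring, read.id, backbone_only.id)
            if aln is not None and (best is None or aln.score > best.score):
                best = aln
        if best is None:
            continue
        matches = sum(n for op, n in best.ops if op == "=")
        span = best.target_end - best.target_start
        if span >= min_anchor and matches / max(span, 1) >= min_identity:
            depth[best.target_start : best.target_end] += 1
    if n_reads == 0:
        warnings.warn("empty read set: backbone breadth is 0", stacklevel=2)
    breadth = float(np.mean(depth >= 1)) if len(depth) else 0.0
    return BackboneScreenResult(
        sample_id=sample_id,
        breadth=breadth,
        mean_depth=float(depth.mean()) if len(depth) else 0.0,
        present=breadth >= breadth_threshold,
        threshold=breadth_threshold,
    )


# ---------------------------------------------------------------------------
# long-read allele assignment


@dataclass
class LongReadAssignment:
    read_id: str
    allele: str  # "Pc", "Pc_star" or "ambiguous"
    score_margin: float
    spans_diagnostic_junction: bool


def assign_long_reads(
    long_reads: Iterable[SequencingRead],
    pc_allele: AlleleModel,
    pcstar_allele: AlleleModel,
    k_bait: int = 15,
    min_hits: int = 3,
    min_margin: float = 20.0,
    anchor: int = 50,
    scoring: Scoring = DEFAULT_SCORING,
    bait_seqs: Optional[Sequence[NucSequence]] = None,
    max_distance_frac: float = 0.45,
) -> Tuple[List[LongReadAssignment], Dict[str, int]]:
    """Assign baited long reads to the Pc vs Pc* allele model.

    A read supports an allele when its alignment to that model beats the
    other model by ``min_margin`` score units AND its footprint is
    diagnostic: on Pc* it overlaps the insertion-unique interval, on Pc it
    spans the integration breakpoint with ``anchor`` bases on both sides.
    Default baits are the insertion-unique blocks of the Pc* model (plasmid
    backbone + extra HDR copy), mirroring a plasmid/HDR-template k-mer bait.
    """
    pc_seq = pc_allele.sequence.bases
    star_seq = pcstar_allele.sequence.bases
    if pc_seq == star_seq:
        raise ValueError("allele models are identical: no diagnostic junction")
    ins_start, bp_on_pc_end, ins_end = diff_interval(pc_seq, star_seq)

    if bait_seqs is None:
        bait_seqs = [
            NucSequence("insertion_unique", star_seq[ins_start:ins_end]),
        ]
    index = build_bait_index(list(bait_seqs), k=k_bait)

    assignments: List[LongReadAssignment] = []
    counts = {"Pc": 0, "Pc_star": 0, "ambiguous": 0}
    for read in long_reads:
        if index.count_hits(read.bases, stop_at=min_hits) < min_hits:
            continue
        # a band on the edit distance speeds things up; the model a read does
        # not belong to often exceeds it and simply yields no alignment
        max_dist = int(max_distance_frac * len(read))
        aln_pc = best_strand_alignment(
            read.bases, pc_seq, scoring, read.id, pc_allele.sequence.id,
            max_distance=max_dist,
        )
        aln_star = best_strand_alignment(
            read.bases, star_seq, scoring, read.id, pcstar_allele.sequence.id,
            max_distance=max_dist,
        )
        if aln_pc is None and aln_star is None:
            continue  # baited but unalignable to either model
        score_pc = aln_pc.score if aln_pc else float("-inf")
        score_star = aln_star.score if aln_star else float("-inf")
        margin = abs(score_pc - score_star)  # inf when the band rejects one model
        allele = "ambiguous"
        spans = False
        if score_star > score_pc and aln_star is not None:
            spans = aln_star.target_start < ins_end and aln_star.target_end > ins_start
            if spans and margin >= min_margin:
                allele = "Pc_star"
        elif score_pc > score_star and aln_pc is not None:
            spans = (
                aln_pc.target_start + anchor <= ins_start
                and aln_pc.target_end - anchor >= bp_on_pc_end
            )
            if spans and margin >= min_margin:
                allele = "Pc"
        assignments.append(
            LongReadAssignment(
                read_id=read.id,
                allele=allele,
                score_margin=margin if allele != "ambiguous" else margin,
                spans_diagnostic_junction=spans,
            )
        )
        counts[allele] += 1
    return assignments, counts


# ---------------------------------------------------------------------------
# I/O


def screen_results_to_tsv(results: Sequence[BackboneScreenResult], path) -> None:
    pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "breadth": r.breadth,
                "mean_depth": r.mean_depth,
                "present": r.present,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def assignments_to_tsv(assignments: Sequence[LongReadAssignment], path) -> None:
    pd.DataFrame(
        [
            {"read_id": a.read_id, "allele": a.allele, "margin": a.score_margin}
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)
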