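"""Shared pairwise-alignment machinery.

Two engines sit behind one op-list representation:

* :class:`Bio.Align.PairwiseAligner` (affine gap scores) for locus-scale
  semi-global alignment of short reads, where exact affine optima matter;
* :mod:`edlib` (unit-cost, banded) for genome-wide read placement and for
  noisy long reads, where speed matters and affine scores are recomputed
  from the op list afterwards.

Ops are ``(op, length)`` tuples with ``op`` in ``{"=", "X", "I", "D"}``
following SAM semantics for a read-vs-target alignment: ``=``/``X`` consume
both sequences, ``I`` consumes the read only, ``D`` the target only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Tuple

import edlib
from Bio import Align

Op = Tuple[str, int]

READ_CONSUMING = {"=", "X", "I"}
TARGET_CONSUMING = {"=", "X", "D"}


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scores; a gap of length L scores open + extend*L."""

    match: float = 1.0
    mismatch: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    """A read-vs-target alignment as an explicit op list."""

    read_id: str
    target_id: str
    target_start: int
    target_end: int
    ops: List[Op]
    score: float
    is_supplementary: bool = False
    strand: str = "+"

    @property
    def edit_distance(self) -> int:
        return sum(n for op, n in self.ops if op != "=")

    @property
    def is_pure_match(self) -> bool:
        return all(op == "=" for op, _ in self.ops)

    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)

    def read_span(self) -> int:
        return sum(n for op, n in self.ops if op in READ_CONSUMING)


def score_ops(ops: List[Op], scoring: Scoring = DEFAULT_SCORING) -> float:
    s = 0.0
    for op, n in ops:
        if op == "=":
            s += scoring.match * n
        elif op == "X":
            s += scoring.mismatch * n
        elif op in ("I", "D"):
            s += scoring.gap_open + scoring.gap_extend * n
    return s


def _collapse(ops: List[Op]) -> List[Op]:
    out: List[Op] = []
    for op, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _match_runs(read_seg: str, target_seg: str) -> List[Op]:
    ops: List[Op] = []
    for a, b in zip(read_seg, target_seg):
        ops.append(("=" if a == b else "X", 1))
    return _collapse(ops)


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # biopython charges open on the first gap base; fold the per-base cost in
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    # free overhangs on the (long) target, read aligned end to end
    aligner.end_insertion_score = 0.0
    return aligner


def align_infix(
    read: str,
    target: str,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "read",
    target_id: str = "target",
) -> Alignment:
    """Best affine-gap alignment of the whole read inside the target."""
    aligner = _make_aligner(scoring)
    aln = aligner.align(read, target)[0]
    read_blocks, target_blocks = (
        [tuple(b) for b in aln.aligned[0]],
        [tuple(b) for b in aln.aligned[1]],
    )
    ops: List[Op] = []
    if read_blocks and read_blocks[0][0] > 0:  # unaligned read prefix
        ops.append(("I", read_blocks[0][0]))
    for i, (rb, tb) in enumerate(zip(read_blocks, target_blocks)):
        if i > 0:
            prev_rb, prev_tb = read_blocks[i - 1], target_blocks[i - 1]
            ops.append(("I", rb[0] - prev_rb[1]))
            ops.append(("D", tb[0] - prev_tb[1]))
        ops.extend(_match_runs(read[rb[0] : rb[1]], target[tb[0] : tb[1]]))
    if read_blocks and read_blocks[-1][1] < len(read):
        ops.append(("I", len(read) - read_blocks[-1][1]))
    ops = _collapse(ops)
    t_start = target_blocks[0][0] if target_blocks else 0
    t_end = target_blocks[-1][1] if target_blocks else 0
    return Alignment(
        read_id=read_id,
        target_id=target_id,
        target_start=t_start,
        target_end=t_end,
        ops=ops,
        score=score_ops(ops, scoring),
    )


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _ops_from_edlib(cigar: str, read: str, target: str, t_start: int) -> List[Op]:
    ops: List[Op] = []
    ri, ti = 0, t_start
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        if op in ("=", "X", "M"):
            ops.extend(_match_runs(read[ri : ri + n], target[ti : ti + n]))
            ri += n
            ti += n
        elif op == "I":
            ops.append(("I", n))
            ri += n
        elif op == "D":
            ops.append(("D", n))
            ti += n
    return _collapse(ops)


def align_edlib(
    read: str,
    target: str,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "read",
    target_id: str = "target",
    max_distance: int = -1,
) -> Alignment | None:
    """Best unit-cost infix alignment of read in target (edlib HW mode).

    Returns None when no alignment within ``max_distance`` exists.
    """
    res = edlib.align(read, target, mode="HW", task="path", k=max_distance)
    if res["editDistance"] < 0 or not res.get("locations"):
        return None
    t_start, t_end_incl = res["locations"][0]
    if t_start is None:
        t_start = 0
    ops = _ops_from_edlib(res["cigar"], read, target, t_start)
    return Alignment(
        read_id=read_id,
        target_id=target_id,
        target_start=t_start,
        target_end=t_end_incl + 1,
        ops=ops,
        score=score_ops(ops, scoring),
    )


def align_local(
    read: str,
    target: str,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "read",
    target_id: str = "target",
) -> Alignment | None:
    """Best affine-gap local alignment (read ends may be soft-clipped).

    Ops cover only the aligned segment; clipped read ends are implicit.
    Returns None when nothing aligns with positive score.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    alns = aligner.align(read, target)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    read_blocks = [tuple(b) for b in aln.aligned[0]]
    target_blocks = [tuple(b) for b in aln.aligned[1]]
    ops: List[Op] = []
    for i, (rb, tb) in enumerate(zip(read_blocks, target_blocks)):
        if i > 0:
            prev_rb, prev_tb = read_blocks[i - 1], target_blocks[i - 1]
            ops.append(("I", rb[0] - prev_rb[1]))
            ops.append(("D", tb[0] - prev_tb[1]))
        ops.extend(_match_runs(read[rb[0] : rb[1]], target[tb[0] : tb[1]]))
    ops = _collapse(ops)
    return Alignment(
        read_id=read_id,
        target_id=target_id,
        target_start=target_blocks[0][0],
        target_end=target_blocks[-1][1],
        ops=ops,
        score=score_ops(ops, scoring),
    )


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def best_strand_alignment(
    read: str,
    target: str,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "read",
    target_id: str = "target",
    engine: str = "edlib",
    max_distance: int = -1,
) -> Alignment | None:
    """Align read on both strands, return the higher-scoring alignment."""
    if engine == "edlib":
        fwd = align_edlib(read, target, scoring, read_id, target_id, max_distance)
        rev = align_edlib(
            reverse_complement(read), target, scoring, read_id, target_id, max_distance
        )
    else:
        fwd = align_infix(read, target, scoring, read_id, target_id)
        rev = align_infix(reverse_complement(read), target, scoring, read_id, target_id)
    if rev is not None and (fwd is None or rev.score > fwd.score):
        rev.strand = "-"
        return rev
    return fwd
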