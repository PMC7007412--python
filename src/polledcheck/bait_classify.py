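"""k-mer read baiting and junction-class assignment for the edited locus.

Reads sharing at least ``k`` (default 25) consecutive bases with the
insertion sequence are selected ("baited") and each baited read is assigned
to one of three expected classes by realignment:

* class A — aligns as a pure match to the unedited reference (read lies in
  the internal repeat or spans its 5' junction);
* class B — aligns to the 3' end of the repeat with a deletion matching a
  derived junction signature;
* class C — needs a split (primary + supplementary) alignment on the
  reference but aligns as a pure match across the repeat-repeat junction of
  the amended reference.

Anything else is UNEXPLAINED and reported with its alignments. A separate
scan places baited reads genome-wide and clusters placements away from the
expected locus into candidate ectopic-insertion calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

from ._align import (
    Alignment,
    DEFAULT_SCORING,
    Scoring,
    align_edlib,
    align_infix,
    reverse_complement,
)
from .locus_models import JunctionSignature, NucSequence


@dataclass(frozen=True)
class SequencingRead:
    id: str
    bases: str
    qualities: Optional[Tuple[int, ...]] = None
    mate: Optional[int] = None
    platform: str = "short"

    def __post_init__(self):
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(f"read {self.id}: quality/base length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


class ReadClassLabel(Enum):
    CLASS_A_INTERNAL_OR_5P_PERFECT = "A"
    CLASS_B_3P_WITH_DELETION = "B"
    CLASS_C_SPLIT_RESOLVED_ON_AMENDED = "C"
    UNEXPLAINED = "unexplained"


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class BaitIndex:
    """Canonical k-mer set of the bait sequence(s).

    ``_lookup`` additionally holds both orientations so read k-mers can be
    tested without per-k-mer canonicalization.
    """

    k: int
    kmers: frozenset
    _lookup: frozenset = field(repr=False, default=frozenset())

    def count_hits(self, bases: str, stop_at: Optional[int] = None) -> int:
        hits = 0
        lookup = self._lookup
        k = self.k
        for i in range(len(bases) - k + 1):
            if bases[i : i + k] in lookup:
                hits += 1
                if stop_at is not None and hits >= stop_at:
                    return hits
        return hits


def build_bait_index(baits: Sequence[NucSequence], k: int = 25) -> BaitIndex:
    kmers = set()
    for bait in baits:
        if len(bait) < k:
            raise ValueError(f"bait {bait.id!r} shorter than k={k}")
        seq = bait.bases
        for i in range(len(seq) - k + 1):
            kmers.add(canonical_kmer(seq[i : i + k]))
    lookup = set(kmers) | {reverse_complement(km) for km in kmers}
    return BaitIndex(k=k, kmers=frozenset(kmers), _lookup=frozenset(lookup))


def bait_reads(
    reads: Iterable[SequencingRead], index: BaitIndex, min_hits: int = 1
) -> List[SequencingRead]:
    """Select reads with >= min_hits bait k-mers (order-independent)."""
    return [r for r in reads if index.count_hits(r.bases, stop_at=min_hits) >= min_hits]


# ---------------------------------------------------------------------------
# classification


def _pattern_of(aln: Alignment) -> Tuple[Tuple[str, Optional[int]], ...]:
    names = {"X": "mismatch", "I": "insertion", "D": "deletion"}
    return tuple(
        ("match", None) if op == "=" else (names[op], n) for op, n in aln.ops
    )


def _matches_signature(aln: Alignment, sig: JunctionSignature) -> bool:
    return _pattern_of(aln) == sig.expected_pattern


def _split_alignment(
    read: str,
    ref: str,
    split_at: int,
    scoring: Scoring,
    read_id: str,
    target_id: str,
    min_piece: int = 20,
) -> Optional[List[Alignment]]:
    if split_at < min_piece or len(read) - split_at < min_piece:
        return None
    head = align_infix(read[:split_at], ref, scoring, read_id, target_id)
    tail = align_infix(read[split_at:], ref, scoring, read_id, target_id)
    tail.is_supplementary = True
    return [head, tail]


def classify_read(
    read: SequencingRead,
    ref_locus: NucSequence,
    amended_locus: NucSequence,
    signatures: Sequence[JunctionSignature],
    scoring: Scoring = DEFAULT_SCORING,
    max_snps: int = 0,
) -> Tuple[ReadClassLabel, List[Alignment]]:
    """Assign a baited read to one of the three expected junction classes.

    ``max_snps`` mismatches are tolerated in the pure-match tests (default 0:
    the strict contract for error-free reads). Both read orientations are
    tried; the label is orientation-invariant.
    """
    if not read.bases:
        raise ValueError(f"read {read.id} is empty")

    def best_orientation(target: NucSequence) -> Alignment:
        fwd = align_infix(read.bases, target.bases, scoring, read.id, target.id)
        rev = align_infix(
            reverse_complement(read.bases), target.bases, scoring, read.id, target.id
        )
        if rev.score > fwd.score:
            rev.strand = "-"
            return rev
        return fwd

    def near_pure(aln: Alignment) -> bool:
        snps = sum(n for op, n in aln.ops if op == "X")
        indels = sum(n for op, n in aln.ops if op in ("I", "D"))
        return indels == 0 and snps <= max_snps

    aln_ref = best_orientation(ref_locus)
    if near_pure(aln_ref):
        return ReadClassLabel.CLASS_A_INTERNAL_OR_5P_PERFECT, [aln_ref]

    # class B: single alignment matching a derived deletion signature
    for sig in signatures:
        if sig.target != "reference":
            continue
        if any(op == "deletion" for op, _ in sig.expected_pattern) and _matches_signature(
            aln_ref, sig
        ):
            return ReadClassLabel.CLASS_B_3P_WITH_DELETION, [aln_ref]

    aln_amended = best_orientation(amended_locus)
    if near_pure(aln_amended):
        # resolves only on the amended locus; report the split placement on
        # the reference (primary + supplementary), split at the junction the
        # read spans
        oriented = (
            read.bases if aln_amended.strand == "+" else reverse_complement(read.bases)
        )
        alns: List[Alignment] = [aln_amended]
        for sig in signatures:
            if sig.target != "amended_reference":
                continue
            j = int(sig.junction_label.rsplit("_", 1)[1])
            if aln_amended.target_start < j < aln_amended.target_end:
                split = _split_alignment(
                    oriented,
                    ref_locus.bases,
                    j - aln_amended.target_start,
                    scoring,
                    read.id,
                    ref_locus.id,
                )
                if split:
                    alns.extend(split)
                break
        return ReadClassLabel.CLASS_C_SPLIT_RESOLVED_ON_AMENDED, alns

    return ReadClassLabel.UNEXPLAINED, [aln_ref, aln_amended]


# ---------------------------------------------------------------------------
# ectopic insertion detection


@dataclass
class InsertionSiteCall:
    contig: str
    window_start: int
    window_end: int
    supporting_read_ids: List[str]
    mean_score: float

    @property
    def support(self) -> int:
        return len(self.supporting_read_ids)


def detect_ectopic_insertions(
    baited: Sequence[SequencingRead],
    genome: Dict[str, str],
    expected_window: Tuple[str, int, int],
    min_support: int = 3,
    scoring: Scoring = DEFAULT_SCORING,
    cluster_gap: Optional[int] = None,
) -> List[InsertionSiteCall]:
    """Cluster best genome-wide placements of baited reads outside the
    expected locus window into candidate ectopic insertion sites.

    An empty return means the insertion sequence is present only at the
    expected position.
    """
    if expected_window is None:
        raise ValueError("expected_window is required")
    exp_contig, exp_start, exp_end = expected_window
    placements = []  # (contig, start, end, read_id, score)
    read_len_max = 1
    for read in baited:
        read_len_max = max(read_len_max, len(read))
        best = None
        for contig, seq in genome.items():
            for strand_seq in (read.bases, reverse_complement(read.bases)):
                aln = align_edlib(strand_seq, seq, scoring, read.id, contig)
                if aln is not None and (best is None or aln.score > best[4]):
                    best = (contig, aln.target_start, aln.target_end, read.id, aln.score)
        if best is None:
            continue
        contig, start, end, rid, score = best
        if contig == exp_contig and start < exp_end and end > exp_start:
            continue  # expected position
        placements.append(best)

    if cluster_gap is None:
        cluster_gap = read_len_max
    placements.sort(key=lambda p: (p[0], p[1]))
    calls: List[InsertionSiteCall] = []
    cluster: List[tuple] = []

    def flush():
        if len(cluster) >= min_support:
            calls.append(
                InsertionSiteCall(
                    contig=cluster[0][0],
                    window_start=min(p[1] for p in cluster),
                    window_end=max(p[2] for p in cluster),
                    supporting_read_ids=[p[3] for p in cluster],
                    mean_score=sum(p[4] for p in cluster) / len(cluster),
                )
            )

    for p in placements:
        if cluster and (p[0] != cluster[-1][0] or p[1] - cluster[-1][2] > cluster_gap):
            flush()
            cluster = []
        cluster.append(p)
    if cluster:
        flush()
    return calls


# ---------------------------------------------------------------------------
# I/O


def read_fastq(path, platform: str = "short") -> List[SequencingRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations.get("phred_quality")
        reads.append(
            SequencingRead(
                id=rec.id,
                bases=str(rec.seq).upper(),
                qualities=tuple(quals) if quals else None,
                platform=platform,
            )
        )
    return reads


def classification_to_tsv(
    rows: Sequence[Tuple[SequencingRead, ReadClassLabel, List[Alignment]]], path
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tclass\ttarget\tstart\tcigar\tscore\n")
        for read, label, alns in rows:
            primary = alns[0]
            fh.write(
                f"{read.id}\t{label.value}\t{primary.target_id}\t"
                f"{primary.target_start}\t{primary.cigar()}\t{primary.score:g}\n"
            )


def insertion_calls_to_bed(calls: Sequence[InsertionSiteCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.window_start}\t{c.window_end}\t"
                f"ectopic_insertion\t{c.support}\t+\n"
            )


def class_counts(labels: Iterable[ReadClassLabel]) -> Dict[str, int]:
    counts = {label.value: 0 for label in ReadClassLabel}
    for label in labels:
        counts[label.value] += 1
    return counts
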