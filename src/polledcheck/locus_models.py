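"""Allele models of the bovine POLLED locus and their junction signatures.

Three alleles are modelled:

* ``p`` — the wild-type (horned) locus, carrying one copy of a 212-bp repeat
  followed by a 10-bp segment (``CTGGTATTCT``);
* ``Pc`` — the Celtic POLLED allele, in which the repeat is duplicated in
  place of the 10-bp segment (net length change +202 bp);
* ``Pc_star`` — the unintended allele carrying the Celtic edit plus the
  donor-plasmid backbone (~3.9 kb) and a second copy of the HDR template.

Coordinates are 0-based half-open throughout; FASTA/BED I/O converts at the
boundary. Junction signatures — the alignment-op pattern an error-free read
spanning an allele junction produces against the unedited reference and
against the amended reference — are derived by actually aligning synthetic
spanning reads, never hard-coded, so signature lengths (e.g. the deletion a
3'-junction read shows) emerge from the sequences themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import Alignment, Op, Scoring, DEFAULT_SCORING, align_infix, reverse_complement

ALPHABET = set("ACGTN")

DEFAULT_REPEAT_LEN = 212
DEFAULT_REPLACED_SEQ = "CTGGTATTCT"


class EditSpecError(ValueError):
    """The edit specification contradicts the supplied wild-type sequence."""


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    bases: str

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases.upper()) - ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid characters: {sorted(bad)}")
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self, new_id: Optional[str] = None) -> "NucSequence":
        return NucSequence(new_id or f"{self.id}_rc", reverse_complement(self.bases))


@dataclass(frozen=True)
class CelticEditSpec:
    """Coordinates of the repeat and the segment it replaces on the wild locus.

    The replaced segment must sit immediately 3' of the repeat (as in the
    locus geometry); set ``require_adjacent=False`` to relax for generality.
    """

    repeat_start: int
    repeat_end: int
    replaced_start: int
    replaced_end: int
    replaced_seq: Optional[str] = DEFAULT_REPLACED_SEQ
    require_adjacent: bool = True

    def __post_init__(self):
        if not (0 <= self.repeat_start < self.repeat_end <= self.replaced_start < self.replaced_end):
            raise EditSpecError("edit coordinates must be ordered and non-empty")
        if self.require_adjacent and self.repeat_end != self.replaced_start:
            raise EditSpecError(
                f"replaced segment must be immediately 3' of the repeat "
                f"(repeat_end={self.repeat_end}, replaced_start={self.replaced_start})"
            )

    @property
    def repeat_len(self) -> int:
        return self.repeat_end - self.repeat_start

    @property
    def replaced_len(self) -> int:
        return self.replaced_end - self.replaced_start

    def validate_against(self, wild: NucSequence) -> None:
        if self.replaced_end > len(wild):
            raise EditSpecError(
                f"replaced segment end {self.replaced_end} beyond locus length {len(wild)}"
            )
        if self.replaced_seq is not None:
            found = wild.bases[self.replaced_start : self.replaced_end]
            if found != self.replaced_seq.upper():
                for i, (a, b) in enumerate(zip(found, self.replaced_seq.upper())):
                    if a != b:
                        raise EditSpecError(
                            f"wild-type bases at replaced segment differ from expected "
                            f"at offset {self.replaced_start + i}: found {a}, expected {b}"
                        )
                raise EditSpecError("replaced segment length mismatch")


Feature = Tuple[str, int, int]


@dataclass
class AlleleModel:
    """One allele of the edited locus with half-open feature annotations."""

    name: str  # "p", "Pc" or "Pc_star"
    sequence: NucSequence
    features: List[Feature] = field(default_factory=list)

    def __post_init__(self):
        if self.name not in ("p", "Pc", "Pc_star"):
            raise ValueError(f"unknown allele name {self.name!r}")
        labels = [f[0] for f in self.features]
        if len(labels) != len(set(labels)):
            raise ValueError("feature labels must be unique")
        for label, start, end in self.features:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"feature {label} out of sequence bounds")

    def feature(self, label: str) -> Feature:
        for f in self.features:
            if f[0] == label:
                return f
        raise KeyError(label)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlasmidIntegrationSpec:
    """Backbone + extra HDR-template copy inserted into the Celtic allele.

    The true block order/orientation at the integration site is a parameter
    (default: forward backbone then the extra HDR copy, immediately 3' of the
    second repeat copy, i.e. ``insertion_offset`` = end of repeat_copy2).
    """

    backbone: NucSequence
    hdr_template: NucSequence
    insertion_offset: int
    orientation: str = "forward"
    arrangement: Tuple[str, ...] = ("backbone", "hdr_copy")

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        if self.arrangement.count("backbone") != 1 or self.arrangement.count("hdr_copy") != 1:
            raise ValueError("arrangement must contain exactly one backbone and one hdr_copy block")


@dataclass(frozen=True)
class JunctionSignature:
    """Expected alignment-op pattern of an error-free read spanning a junction.

    ``expected_pattern`` entries are ``(op_class, length)`` with op_class in
    {match, mismatch, deletion, insertion, clip}; length None means variable.
    ``target`` names which sequence the pattern applies to.
    """

    junction_label: str
    expected_pattern: Tuple[Tuple[str, Optional[int]], ...]
    target: str  # "reference" or "amended_reference"

    def __post_init__(self):
        for op, length in self.expected_pattern:
            if op in ("deletion", "insertion") and (length is None or length <= 0):
                raise ValueError("deletion/insertion lengths must be positive")


# ---------------------------------------------------------------------------
# allele construction


def apply_celtic_edit(wild_locus: NucSequence, spec: CelticEditSpec) -> AlleleModel:
    """Duplicate the repeat in place of the replaced segment (p -> Pc)."""
    spec.validate_against(wild_locus)
    w = wild_locus.bases
    repeat = w[spec.repeat_start : spec.repeat_end]
    edited = (
        w[: spec.replaced_start] + repeat + w[spec.replaced_end :]
    )
    copy2_start = spec.replaced_start
    features = [
        ("repeat_copy1", spec.repeat_start, spec.repeat_end),
        ("repeat_copy2", copy2_start, copy2_start + len(repeat)),
    ]
    return AlleleModel(
        name="Pc",
        sequence=NucSequence(f"{wild_locus.id}_Pc", edited),
        features=features,
    )


def wild_allele(wild_locus: NucSequence, spec: Optional[CelticEditSpec] = None) -> AlleleModel:
    """Wrap a wild-type locus as the p allele (annotating the repeat if known)."""
    features = []
    if spec is not None:
        spec.validate_against(wild_locus)
        features = [
            ("repeat_copy1", spec.repeat_start, spec.repeat_end),
            ("replaced_segment", spec.replaced_start, spec.replaced_end),
        ]
    return AlleleModel(name="p", sequence=wild_locus, features=features)


def build_plasmid_allele(pc: AlleleModel, integ: PlasmidIntegrationSpec) -> AlleleModel:
    """Insert the plasmid backbone and a second HDR-template copy (Pc -> Pc*)."""
    if pc.name != "Pc":
        raise ValueError("plasmid integration is modelled on the Pc allele")
    if not (0 <= integ.insertion_offset <= len(pc)):
        raise IndexError(
            f"insertion_offset {integ.insertion_offset} outside allele of length {len(pc)}"
        )
    backbone_seq = (
        integ.backbone.bases
        if integ.orientation == "forward"
        else reverse_complement(integ.backbone.bases)
    )
    block_seqs = {"backbone": backbone_seq, "hdr_copy": integ.hdr_template.bases}
    inserted = "".join(block_seqs[b] for b in integ.arrangement)
    seq = pc.sequence.bases
    new_seq = seq[: integ.insertion_offset] + inserted + seq[integ.insertion_offset :]

    features: List[Feature] = []
    for label, start, end in pc.features:
        if end <= integ.insertion_offset:
            features.append((label, start, end))
        elif start >= integ.insertion_offset:
            features.append((label, start + len(inserted), end + len(inserted)))
        else:  # insertion falls inside an existing feature: split annotation
            features.append((f"{label}_5p", start, integ.insertion_offset))
            features.append(
                (f"{label}_3p", integ.insertion_offset + len(inserted), end + len(inserted))
            )
    pos = integ.insertion_offset
    for block in integ.arrangement:
        features.append((block, pos, pos + len(block_seqs[block])))
        pos += len(block_seqs[block])
    return AlleleModel(
        name="Pc_star",
        sequence=NucSequence(f"{pc.sequence.id}_star", new_seq),
        features=sorted(features, key=lambda f: (f[1], f[2])),
    )


# ---------------------------------------------------------------------------
# diffing and junctions


def diff_interval(ref: str, alt: str) -> Tuple[int, int, int]:
    """Locate the single divergent interval between two sequences.

    Returns ``(start, ref_end, alt_end)`` such that ``ref[:start] == alt[:start]``
    and ``ref[ref_end:] == alt[alt_end:]`` with the interval minimal.
    Identical sequences return ``(L, L, L)``.
    """
    if ref == alt:
        n = len(ref)
        return n, n, n
    lcp = 0
    while lcp < min(len(ref), len(alt)) and ref[lcp] == alt[lcp]:
        lcp += 1
    lcs = 0
    while (
        lcs < min(len(ref), len(alt)) - lcp
        and ref[len(ref) - 1 - lcs] == alt[len(alt) - 1 - lcs]
    ):
        lcs += 1
    return lcp, len(ref) - lcs, len(alt) - lcs


def diff_single_replacement(wild: NucSequence, edited: NucSequence) -> Tuple[int, str, str]:
    """Recover the single replacement event turning wild into edited.

    Returns ``(start, removed, inserted)``; raises if the sequences are equal.
    """
    if wild.bases == edited.bases:
        raise ValueError("sequences are identical; no replacement event")
    start, ref_end, alt_end = diff_interval(wild.bases, edited.bases)
    return start, wild.bases[start:ref_end], edited.bases[start:alt_end]


def _classify_ops(ops: List[Op]) -> Tuple[Tuple[str, Optional[int]], ...]:
    names = {"=": "match", "X": "mismatch", "I": "insertion", "D": "deletion"}
    out: List[Tuple[str, Optional[int]]] = []
    for op, n in ops:
        if op == "=":
            out.append(("match", None))
        else:
            out.append((names[op], int(n)))
    return tuple(out)


def derive_junction_signatures(
    ref_locus: NucSequence,
    allele: AlleleModel,
    read_len: int,
    scoring: Scoring = DEFAULT_SCORING,
    max_pattern_distance_frac: float = 0.25,
) -> List[JunctionSignature]:
    """Derive the alignment patterns junction-spanning error-free reads show.

    For each junction (boundary of divergent sequence or of an annotated
    feature inside it) a synthetic error-free read of ``read_len`` centred on
    the junction is aligned to the unedited reference; the emergent minimal
    pattern is recorded. Junctions whose best single alignment is degenerate
    (cost above ``max_pattern_distance_frac * read_len``) are reported as
    split/clip signatures against the reference together with a pure-match
    signature against the amended reference.
    """
    ref = ref_locus.bases
    alt = allele.sequence.bases
    if ref == alt:
        return []
    start, ref_end, alt_end = diff_interval(ref, alt)
    junctions = {start, alt_end}
    for label, f_start, f_end in allele.features:
        for pos in (f_start, f_end):
            if start <= pos <= alt_end:
                junctions.add(pos)

    signatures: List[JunctionSignature] = []
    half = read_len // 2
    for j in sorted(junctions):
        left = j - half
        right = left + read_len
        if left < 0 or right > len(alt):
            warnings.warn(
                f"junction at {j}: no spanning read of length {read_len} fits "
                f"within the allele; signature omitted",
                stacklevel=2,
            )
            continue
        read = alt[left:right]
        label = f"junction_{j}"
        aln = align_infix(read, ref, scoring, read_id=label, target_id=ref_locus.id)
        if aln.is_pure_match:
            continue  # not a variant junction for reads of this length
        if aln.edit_distance <= max_pattern_distance_frac * read_len:
            signatures.append(
                JunctionSignature(label, _classify_ops(aln.ops), target="reference")
            )
        else:
            # no sensible linear alignment: a real mapper reports a split read
            signatures.append(
                JunctionSignature(
                    label,
                    (("match", None), ("clip", None)),
                    target="reference",
                )
            )
        signatures.append(
            JunctionSignature(label, (("match", None),), target="amended_reference")
        )
    return signatures


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> List[NucSequence]:
    return [NucSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[NucSequence], path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def write_features_bed(allele: AlleleModel, path) -> None:
    """Export feature annotations as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for label, start, end in allele.features:
            fh.write(
                f"{allele.sequence.id}\t{start}\t{end}\t{label}\t0\t+\n"
            )
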