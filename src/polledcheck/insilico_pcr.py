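"""In-silico PCR for the polled/horned genotyping screen.

Predicts primer binding sites and amplicon sizes on allele templates and
turns the resulting band patterns into genotype calls: the wild-type locus
yields a short product (389 bp in the published screen), the Celtic allele
the same product plus the 202-bp net insertion (591 bp), and heterozygotes
show both bands. Also carries the qPCR standard-curve efficiency formula
E = 10^(-1/s) - 1 with the 90% validation gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from ._align import reverse_complement
from .locus_models import NucSequence

MIN_PRIMER_LEN = 15


@dataclass(frozen=True)
class PrimerPair:
    """A primer pair; the reverse primer is given 5'->3' as synthesized."""

    name: str
    forward: NucSequence
    reverse: NucSequence
    max_mismatches: int = 0
    require_3prime_anchor: bool = True
    three_prime_anchor_len: int = 3

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if len(p) < MIN_PRIMER_LEN:
                raise ValueError(f"primer {p.id!r} shorter than {MIN_PRIMER_LEN} nt")
            if self.max_mismatches >= len(p):
                raise ValueError("max_mismatches must be smaller than primer length")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class AmpliconCall:
    """A predicted PCR product on a template (half-open coordinates)."""

    template_id: str
    start: int
    end: int
    forward_site: int
    reverse_site: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _binding_sites(
    template: str, primer: str, max_mismatches: int, anchor: int
) -> List[int]:
    """All start offsets where primer binds the top strand 5'->3'.

    Mismatches are allowed up to ``max_mismatches`` but never within the
    3'-terminal ``anchor`` bases (polymerase extension requires an anchored
    3' end).
    """
    sites = []
    plen = len(primer)
    if max_mismatches == 0:
        pos = template.find(primer)
        while pos != -1:
            sites.append(pos)
            pos = template.find(primer, pos + 1)
        return sites
    for pos in range(len(template) - plen + 1):
        window = template[pos : pos + plen]
        mm = 0
        ok = True
        for i in range(plen):
            if window[i] != primer[i]:
                if i >= plen - anchor:
                    ok = False
                    break
                mm += 1
                if mm > max_mismatches:
                    ok = False
                    break
        if ok:
            sites.append(pos)
    return sites


def predict_amplicons(
    template: NucSequence, pair: PrimerPair, max_len: int = 5000
) -> List[AmpliconCall]:
    """Every forward/reverse site pairing giving a product of <= max_len bp."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    anchor = pair.three_prime_anchor_len if pair.require_3prime_anchor else 0
    seq = template.bases
    fwd_sites = _binding_sites(seq, pair.forward.bases, pair.max_mismatches, anchor)
    # reverse primer binds the bottom strand: search its reverse complement on
    # the top strand; the 3' anchor of the primer is the 5' end of that motif
    rev_motif = reverse_complement(pair.reverse.bases)
    rev_sites = _rev_sites(seq, rev_motif, pair.max_mismatches, anchor)
    calls = []
    min_product = len(pair.forward) + len(pair.reverse)
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(pair.reverse)
            if f < r and end - f <= max_len and end - f >= min_product:
                calls.append(
                    AmpliconCall(
                        template_id=template.id,
                        start=f,
                        end=end,
                        forward_site=f,
                        reverse_site=r,
                    )
                )
    calls.sort(key=lambda c: (c.start, c.length))
    return calls


def _rev_sites(template: str, rev_motif: str, max_mismatches: int, anchor: int) -> List[int]:
    # on the top strand the motif's FIRST `anchor` bases are the primer 3' end
    sites = []
    plen = len(rev_motif)
    if max_mismatches == 0:
        pos = template.find(rev_motif)
        while pos != -1:
            sites.append(pos)
            pos = template.find(rev_motif, pos + 1)
        return sites
    for pos in range(len(template) - plen + 1):
        window = template[pos : pos + plen]
        mm = 0
        ok = True
        for i in range(plen):
            if window[i] != rev_motif[i]:
                if i < anchor:
                    ok = False
                    break
                mm += 1
                if mm > max_mismatches:
                    ok = False
                    break
        if ok:
            sites.append(pos)
    return sites


def design_screen_pair(
    wild: NucSequence,
    repeat_start: int,
    replaced_end: int,
    wild_product: int = 389,
    primer_len: int = 20,
    upstream_gap: int = 5,
    name: str = "screen",
) -> PrimerPair:
    """Design a variant-spanning primer pair calibrated to a wild-type
    product of ``wild_product`` bp.

    The forward primer sits just upstream of the repeat (so the duplicated
    repeat cannot create a second binding site) and the reverse primer is
    placed so the product spans the replaced segment. On the Celtic allele
    the same pair yields ``wild_product`` plus the net insertion length.
    """
    f_start = repeat_start - primer_len - upstream_gap
    if f_start < 0:
        raise ValueError("not enough sequence upstream of the repeat for a primer")
    r_end = f_start + wild_product
    if r_end > len(wild):
        raise ValueError("not enough sequence downstream for the requested product")
    if r_end - primer_len < replaced_end:
        raise ValueError("requested product does not span the variant region")
    fwd = wild.bases[f_start : f_start + primer_len]
    rev = reverse_complement(wild.bases[r_end - primer_len : r_end])
    return PrimerPair(name, NucSequence(f"{name}_F", fwd), NucSequence(f"{name}_R", rev))


# ---------------------------------------------------------------------------
# band-pattern genotyping


def genotype_from_bands(
    amplicons_per_allele: Dict[str, Sequence[int]],
    polled_band: int = 591,
    horned_band: int = 389,
    tolerance: int = 5,
) -> str:
    """Call a genotype from the band lengths each allele produces.

    Bands within ``tolerance`` bp of the configured polled/horned lengths are
    binned to those classes; {polled only} -> PcPc, {horned only} -> pp,
    {both} -> Pcp, anything else -> "uninterpretable".
    """
    if not amplicons_per_allele:
        raise ValueError("no alleles supplied")
    if len(amplicons_per_allele) not in (1, 2):
        raise ValueError("genotype calling expects 1 or 2 alleles")
    classes = set()
    for lengths in amplicons_per_allele.values():
        for length in lengths:
            if abs(length - polled_band) <= tolerance:
                classes.add("polled")
            elif abs(length - horned_band) <= tolerance:
                classes.add("horned")
            else:
                classes.add("other")
    if classes == {"polled"}:
        return "PcPc"
    if classes == {"horned"}:
        return "pp"
    if classes == {"polled", "horned"}:
        return "Pcp"
    return "uninterpretable"


# ---------------------------------------------------------------------------
# qPCR efficiency


def amplification_efficiency(slope: float) -> float:
    """Standard-curve amplification efficiency, E = 10^(-1/s) - 1."""
    if slope == 0:
        raise ZeroDivisionError("standard-curve slope must be nonzero")
    return 10.0 ** (-1.0 / slope) - 1.0


def efficiency_passes(slope: float, threshold: float = 0.90) -> bool:
    """Validation gate: efficiency must exceed the threshold (default 90%)."""
    return amplification_efficiency(slope) > threshold


# ---------------------------------------------------------------------------
# I/O


def read_primers_tsv(path) -> List[PrimerPair]:
    """Primers from TSV with columns name, forward, reverse."""
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PrimerPair(
                name=str(row["name"]),
                forward=NucSequence(f"{row['name']}_F", str(row["forward"])),
                reverse=NucSequence(f"{row['name']}_R", str(row["reverse"])),
            )
        )
    return pairs


def amplicons_to_tsv(calls: Iterable[AmpliconCall], path) -> None:
    df = pd.DataFrame(
        [
            {
                "template": c.template_id,
                "start": c.start,
                "end": c.end,
                "length": c.length,
            }
            for c in calls
        ]
    )
    df.to_csv(path, sep="\t", index=False)
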