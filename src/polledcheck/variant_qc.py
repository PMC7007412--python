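"""Variant-level hard filters and cohort site filters.

The hard-filter engine applies the study's GATK-style thresholds to VCF-like
records (QD, FS, SOR, ReadPosRankSum and DP for all variants; MQ and
MQRankSum for SNPs; InbreedingCoeff for indels). A missing INFO annotation
leaves its rule unevaluated (the record passes that rule), matching common
hard-filtering semantics. Site filters then drop non-biallelic sites, sites
with genotype rate below 95% and sites with minor allele frequency below 5%,
in that order, reporting per-rule exclusion counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

MISSING = -1

#: rule name -> (info key, direction, threshold, applies_to)
#: direction "lt" fails when value < threshold; "gt" fails when value > threshold
DEFAULT_THRESHOLDS: Dict[str, Tuple[str, str, float, str]] = {
    "QD": ("QD", "lt", 2.0, "all"),
    "FS": ("FS", "gt", 60.0, "all"),
    "SOR": ("SOR", "gt", 4.0, "all"),
    "ReadPosRankSum": ("ReadPosRankSum", "lt", -8.0, "all"),
    "DP": ("DP", "gt", 3105.0, "all"),  # cohort-summed depth upper bound
    "MQ": ("MQ", "lt", 40.0, "SNP"),
    "MQRankSum": ("MQRankSum", "lt", -12.5, "SNP"),
    "InbreedingCoeff": ("InbreedingCoeff", "lt", -0.8, "indel"),
}


@dataclass
class VariantRecord:
    contig: str
    pos: int  # 0-based internally; +1 on VCF I/O
    ref: str
    alts: Tuple[str, ...]
    info: Dict[str, float] = field(default_factory=dict)
    genotypes: Optional[np.ndarray] = None  # per-sample 0/1/2, MISSING=-1

    @property
    def vtype(self) -> str:
        if all(len(a) == len(self.ref) == 1 for a in self.alts):
            return "SNP"
        return "indel"

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass(frozen=True)
class FilterVerdict:
    reasons: Tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.reasons


def hard_filter(
    rec: VariantRecord,
    thresholds: Optional[Dict[str, Tuple[str, str, float, str]]] = None,
) -> FilterVerdict:
    """Evaluate every applicable hard-filter rule; missing INFO keys pass."""
    rules = thresholds if thresholds is not None else DEFAULT_THRESHOLDS
    vtype = rec.vtype
    reasons = []
    for name, (key, direction, cutoff, applies_to) in rules.items():
        if applies_to != "all" and applies_to != vtype:
            continue
        value = rec.info.get(key)
        if value is None:
            continue
        if (direction == "lt" and value < cutoff) or (
            direction == "gt" and value > cutoff
        ):
            reasons.append(name)
    return FilterVerdict(tuple(reasons))


# ---------------------------------------------------------------------------
# cohort site filters (operate on the genotype matrix from trio_mendel)


def site_filters(
    matrix: "GenotypeMatrix",
    min_genotype_rate: float = 0.95,
    min_maf: float = 0.05,
    biallelic_only: bool = True,
):
    """Apply the study's site filters in order; returns (matrix, counts).

    Order: biallelic -> genotype rate -> MAF, each rule seeing only sites
    that survived the previous one. Thresholds are strict "<" exclusions:
    a site at exactly the threshold is retained. MAF uses allele counts over
    non-missing genotypes.
    """
    from .trio_mendel import GenotypeMatrix  # deferred: avoids import cycle

    if matrix.n_sites == 0:
        raise ValueError("empty genotype matrix")
    g = matrix.genotypes
    keep = np.ones(matrix.n_sites, dtype=bool)
    counts = {"non_biallelic": 0, "genotype_rate": 0, "maf": 0}

    if biallelic_only and matrix.biallelic is not None:
        drop = ~matrix.biallelic
        counts["non_biallelic"] = int(drop.sum())
        keep &= ~drop

    called = g != MISSING
    rate = called.sum(axis=1) / g.shape[1]
    drop = keep & (rate < min_genotype_rate)
    counts["genotype_rate"] = int(drop.sum())
    keep &= ~drop

    with np.errstate(invalid="ignore"):
        alt_count = np.where(called, g, 0).sum(axis=1)
        n_alleles = 2 * called.sum(axis=1)
        p = np.divide(alt_count, n_alleles, out=np.zeros(len(g)), where=n_alleles > 0)
    maf = np.minimum(p, 1 - p)
    drop = keep & (maf < min_maf)
    counts["maf"] = int(drop.sum())
    keep &= ~drop

    if not keep.any():
        warnings.warn("all sites removed by site filters", stacklevel=2)
    return matrix.subset_sites(np.flatnonzero(keep)), counts


# ---------------------------------------------------------------------------
# VCF I/O (pysam)


def read_vcf(path) -> List[VariantRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            info = {}
            for key in ("QD", "FS", "SOR", "ReadPosRankSum", "DP", "MQ", "MQRankSum", "InbreedingCoeff"):
                if key in rec.info:
                    val = rec.info[key]
                    info[key] = float(val[0] if isinstance(val, tuple) else val)
            genotypes = None
            if sample_ids:
                genotypes = np.full(len(sample_ids), MISSING, dtype=np.int8)
                for i, sid in enumerate(sample_ids):
                    gt = rec.samples[sid].get("GT")
                    if gt is not None and None not in gt:
                        genotypes[i] = sum(min(a, 1) for a in gt)
            records.append(
                VariantRecord(
                    contig=rec.contig,
                    pos=rec.pos - 1,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    info=info,
                    genotypes=genotypes,
                )
            )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    verdicts: Sequence[FilterVerdict],
    path,
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write records with the FILTER column set to failed rule names."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">')
    header.add_line('##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand">')
    header.add_line('##INFO=<ID=SOR,Number=1,Type=Float,Description="StrandOddsRatio">')
    header.add_line('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="ReadPosRankSum">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMSMappingQuality">')
    header.add_line('##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQRankSum">')
    header.add_line('##INFO=<ID=InbreedingCoeff,Number=1,Type=Float,Description="InbreedingCoeff">')
    for name in DEFAULT_THRESHOLDS:
        header.add_line(f'##FILTER=<ID={name},Description="Hard filter {name}">')
    seen = contigs or {}
    if not seen:
        for rec in records:
            seen[rec.contig] = max(seen.get(rec.contig, 0), rec.pos + 2)
    for contig, length in seen.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec, verdict in zip(records, verdicts):
            row = out.new_record(
                contig=rec.contig,
                start=rec.pos,
                alleles=(rec.ref, *rec.alts),
            )
            for key, value in rec.info.items():
                row.info[key] = int(value) if key == "DP" else value
            if verdict.passed:
                row.filter.add("PASS")
            else:
                for reason in verdict.reasons:
                    row.filter.add(reason)
            out.write(row)
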