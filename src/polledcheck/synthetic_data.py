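"""Synthetic data generation with full ground truth.

Everything the verification pipeline consumes can be simulated here under a
single seeded configuration: a reference genome carrying the polled locus
(a 212-bp repeat followed by the 10-bp segment CTGGTATTCT), per-animal
diploid genomes with any locus genotype (pp, Pcp, Pc*p, PcPc, PcPc*),
paired-end short reads and noisy long reads with recorded origins, and trio
genotype matrices mirroring the study design (28 animals, 12 sire/dam/
offspring trios in four families and three study groups of 6/3/3 trios).
Defaults follow the study conditions: ~20x short-read and 14x long-read
depth, 2x150-bp pairs, 10-kb mean long reads at 10% error, a 3.9-kb plasmid
backbone with a 1.6-kb HDR template, and a 99.8% genotyping rate.

The repeat, backbone and genomic background are random sequences (their real
counterparts are not public); hooks accept user-supplied sequences instead.
Every stochastic call is reproducible from (seed, config) alone.

A packaged fixture additionally ships the published per-trio Mendelian error
counts and the 14,084,653-variant denominator so the published statistics
can be reproduced without any simulation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._align import reverse_complement
from .bait_classify import SequencingRead
from .locus_models import (
    AlleleModel,
    CelticEditSpec,
    NucSequence,
    apply_celtic_edit,
    build_plasmid_allele,
    PlasmidIntegrationSpec,
    wild_allele,
    DEFAULT_REPLACED_SEQ,
)
from .trio_mendel import GenotypeMatrix, MendelResult, TrioSpec
from .variant_qc import VariantRecord

TABLE1_DENOMINATOR = 14_084_653
_TABLE1_SHA256 = "f7ffbb4920718b66b7a453921d912c53db9014b8e94699487fdb8094eb32a694"

BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class LocusParams:
    genome_length: int = 1_000_000
    locus_start: int = 500_000  # repeat start on the reference contig
    repeat_len: int = 212
    replaced_seq: str = DEFAULT_REPLACED_SEQ
    backbone_len: int = 3_900
    hdr_len: int = 1_600
    locus_flank: int = 2_000  # flank kept in locus-scale alignment targets
    decoy_length: int = 50_000
    repeat_seq: Optional[str] = None  # user-supplied real repeat, if available
    backbone_seq: Optional[str] = None


@dataclass(frozen=True)
class ShortReadParams:
    depth: float = 20.0  # diploid depth
    read_len: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 60.0
    error: float = 0.001


@dataclass(frozen=True)
class LongReadParams:
    depth: float = 14.0
    mean_len: float = 10_000.0
    sigma: float = 0.4  # log-normal shape
    error: float = 0.10  # total; split 60/20/20 sub/ins/del


@dataclass(frozen=True)
class TrioParams:
    n_sites: int = 100_000
    contig: str = "chr1"
    contig_length: int = 10_000_000
    eps: float = 0.005  # symmetric genotyping error rate
    missing_rate: float = 0.002  # matches the cohort's 99.8% genotyping rate
    freq: Tuple = ("uniform", 0.05, 0.95)
    fst: float = 0.0  # per-family Balding-Nichols divergence (0 = one population)
    hotspot_bins: Tuple[Tuple[str, int], ...] = ()
    hotspot_boost: float = 50.0
    window: int = 10_000


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    locus: LocusParams = field(default_factory=LocusParams)
    short: ShortReadParams = field(default_factory=ShortReadParams)
    long: LongReadParams = field(default_factory=LongReadParams)
    trio: TrioParams = field(default_factory=TrioParams)

    def __post_init__(self):
        for rate in (self.short.error, self.long.error, self.trio.eps, self.trio.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for depth in (self.short.depth, self.long.depth):
            if depth <= 0:
                raise ValueError("depths must be positive")


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{cfg_seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "little"))


def random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------------------
# genomes


@dataclass
class GenomeTruth:
    edit_spec: CelticEditSpec  # coordinates on the locus window
    window_start: int  # offset of the locus window on chr1
    ref_locus: NucSequence  # reference locus window (alignment target)
    repeat: NucSequence
    backbone: NucSequence
    hdr_template: NucSequence
    alleles: Dict[str, AlleleModel]  # locus-window-scale p / Pc / Pc_star models
    full_haplotypes: Dict[str, NucSequence]  # allele name -> whole-chr1 sequence
    expected_window: Tuple[str, int, int]
    allele_pairs: Dict[str, Tuple[str, str]]  # animal -> haplotype allele names
    ectopic_site: Optional[Tuple[str, int]] = None


@dataclass
class AnimalGenome:
    sample_id: str
    haplotypes: List[NucSequence]  # one NucSequence per contig per haplotype

    def total_length(self) -> int:
        return sum(len(h) for h in self.haplotypes)


GENOTYPE_ALLELES = {
    "pp": ("p", "p"),
    "Pcp": ("Pc", "p"),
    "Pc*p": ("Pc_star", "p"),
    "PcPc": ("Pc", "Pc"),
    "PcPc*": ("Pc", "Pc_star"),
}


def make_genomes(
    cfg: SimulationConfig,
    animals: Mapping[str, str],
    plant_ectopic_in: Optional[str] = None,
) -> Tuple[Dict[str, NucSequence], Dict[str, AnimalGenome], GenomeTruth]:
    """Reference contigs + per-animal diploid genomes + ground truth.

    ``animals`` maps sample id to locus genotype (keys of GENOTYPE_ALLELES).
    ``plant_ectopic_in`` names an animal whose first haplotype receives an
    extra copy of the insertion sequence (the repeat) mid-decoy-contig.
    """
    lp = cfg.locus
    rng = _rng(cfg.seed, "genome")
    repeat = lp.repeat_seq or random_bases(rng, lp.repeat_len)
    background = random_bases(rng, lp.genome_length)
    locus_end = lp.locus_start + len(repeat) + len(lp.replaced_seq)
    if locus_end > lp.genome_length:
        raise ValueError("locus does not fit inside the genome")
    chr1 = (
        background[: lp.locus_start]
        + repeat
        + lp.replaced_seq
        + background[locus_end:]
    )
    reference = {"chr1": NucSequence("chr1", chr1)}
    decoy_seq = None
    if lp.decoy_length:
        decoy_seq = random_bases(rng, lp.decoy_length)
        reference["decoy"] = NucSequence("decoy", decoy_seq)

    # allele models are built on a locus window so alignment targets stay
    # locus-scale; full chr1 haplotypes splice the edited window back in
    ws = max(0, lp.locus_start - lp.locus_flank)
    we = min(lp.genome_length, locus_end + lp.locus_flank)
    ref_locus = NucSequence(f"chr1:{ws}-{we}", chr1[ws:we])
    spec = CelticEditSpec(
        repeat_start=lp.locus_start - ws,
        repeat_end=lp.locus_start - ws + len(repeat),
        replaced_start=lp.locus_start - ws + len(repeat),
        replaced_end=locus_end - ws,
        replaced_seq=lp.replaced_seq,
    )
    p_model = wild_allele(ref_locus, spec)
    pc_model = apply_celtic_edit(ref_locus, spec)
    _, c2s, c2e = pc_model.feature("repeat_copy2")

    hdr_center = (pc_model.feature("repeat_copy1")[1] + c2e) // 2
    hdr_start = max(0, hdr_center - lp.hdr_len // 2)
    hdr_template = NucSequence(
        "hdr_template", pc_model.sequence.bases[hdr_start : hdr_start + lp.hdr_len]
    )
    backbone = NucSequence(
        "backbone", lp.backbone_seq or random_bases(rng, lp.backbone_len)
    )
    integ = PlasmidIntegrationSpec(
        backbone=backbone, hdr_template=hdr_template, insertion_offset=c2e
    )
    pcstar_model = build_plasmid_allele(pc_model, integ)
    full_haplotypes = {
        "p": reference["chr1"],
        "Pc": NucSequence(
            "chr1_Pc", chr1[:ws] + pc_model.sequence.bases + chr1[we:]
        ),
        "Pc_star": NucSequence(
            "chr1_Pc_star", chr1[:ws] + pcstar_model.sequence.bases + chr1[we:]
        ),
    }
    hap_seqs = {name: seq.bases for name, seq in full_haplotypes.items()}

    genomes: Dict[str, AnimalGenome] = {}
    allele_pairs: Dict[str, Tuple[str, str]] = {}
    ectopic_site = None
    for sample, genotype in animals.items():
        if genotype not in GENOTYPE_ALLELES:
            raise ValueError(f"unknown locus genotype {genotype!r} for {sample}")
        pair = GENOTYPE_ALLELES[genotype]
        allele_pairs[sample] = pair
        haplotypes = []
        for h, allele_name in enumerate(pair, start=1):
            haplotypes.append(
                NucSequence(f"{sample}|chr1_h{h}", hap_seqs[allele_name])
            )
            if decoy_seq is not None:
                d = decoy_seq
                if plant_ectopic_in == sample and h == 1:
                    mid = lp.decoy_length // 2
                    d = decoy_seq[:mid] + repeat + decoy_seq[mid:]
                    ectopic_site = ("decoy", mid)
                haplotypes.append(NucSequence(f"{sample}|decoy_h{h}", d))
        genomes[sample] = AnimalGenome(sample_id=sample, haplotypes=haplotypes)

    margin = cfg.short.read_len * 2
    truth = GenomeTruth(
        edit_spec=spec,
        window_start=ws,
        ref_locus=ref_locus,
        repeat=NucSequence("repeat", repeat),
        backbone=backbone,
        hdr_template=hdr_template,
        alleles={"p": p_model, "Pc": pc_model, "Pc_star": pcstar_model},
        full_haplotypes=full_haplotypes,
        expected_window=("chr1", lp.locus_start - margin, locus_end + margin),
        allele_pairs=allele_pairs,
        ectopic_site=ectopic_site,
    )
    return reference, genomes, truth


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadSimResult:
    reads: List[SequencingRead]
    origins: Dict[str, Tuple[str, int, int]]  # read id -> (haplotype id, start, end)


_BASE_TO_INT = {65: 0, 67: 1, 71: 2, 84: 3}


def _mutate_subs(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        codes = np.array([65, 67, 71, 84], dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        lut[[65, 67, 71, 84]] = [0, 1, 2, 3]
        orig = lut[arr[hit]]
        arr[hit] = codes[(orig + rng.integers(1, 4, size=int(hit.sum()))) % 4]
    return arr.tobytes().decode()


def _mutate_with_indels(
    seq: str, sub: float, ins: float, dele: float, rng: np.random.Generator
) -> str:
    arr = np.frombuffer(_mutate_subs(seq, sub, rng).encode(), dtype=np.uint8)
    keep = rng.random(len(arr)) >= dele
    ins_after = rng.random(len(arr)) < ins
    repeats = keep.astype(np.int64) + ins_after.astype(np.int64)
    out = np.repeat(arr, repeats)
    # overwrite the duplicated copies with random bases
    dup_pos = np.cumsum(repeats)[repeats == 2] - 1
    if len(dup_pos):
        codes = np.array([65, 67, 71, 84], dtype=np.uint8)
        out[dup_pos] = codes[rng.integers(0, 4, size=len(dup_pos))]
    return out.tobytes().decode()


def simulate_reads(
    genome: AnimalGenome, cfg: SimulationConfig, mode: str = "short"
) -> ReadSimResult:
    """Seeded read simulation with recorded per-read origin intervals.

    Short mode: proper 2x``read_len`` pairs, insert ~ N(mean, sd), uniform
    start positions, symmetric substitution errors. Long mode: log-normal
    lengths and substitution+indel errors (60/20/20 split of the total rate).
    """
    if mode not in ("short", "long"):
        raise ValueError("mode must be 'short' or 'long'")
    rng = _rng(cfg.seed, f"reads:{mode}:{genome.sample_id}")
    reads: List[SequencingRead] = []
    origins: Dict[str, Tuple[str, int, int]] = {}
    n_haps = max(
        1, len({h.id.split("|")[1].rsplit("_h", 1)[1] for h in genome.haplotypes})
    )
    if mode == "short":
        p = cfg.short
        per_hap_depth = p.depth / n_haps
        for hap in genome.haplotypes:
            L = len(hap)
            n_pairs = int(round(L * per_hap_depth / (2 * p.read_len)))
            if n_pairs == 0:
                continue
            inserts = np.maximum(
                rng.normal(p.insert_mean, p.insert_sd, n_pairs), p.read_len
            ).astype(int)
            starts = rng.integers(0, np.maximum(L - inserts, 1))
            for i in range(n_pairs):
                s, ins_len = int(starts[i]), int(inserts[i])
                frag = hap.bases[s : s + ins_len]
                r1 = _mutate_subs(frag[: p.read_len], p.error, rng)
                r2 = _mutate_subs(
                    reverse_complement(frag[-p.read_len :]), p.error, rng
                )
                rid = f"{hap.id}:{s}:{i}"
                reads.append(SequencingRead(f"{rid}/1", r1, mate=1, platform="short"))
                reads.append(SequencingRead(f"{rid}/2", r2, mate=2, platform="short"))
                origins[f"{rid}/1"] = (hap.id, s, s + min(p.read_len, len(frag)))
                origins[f"{rid}/2"] = (
                    hap.id,
                    s + max(0, ins_len - p.read_len),
                    s + ins_len,
                )
    else:
        p = cfg.long
        per_hap_depth = p.depth / n_haps
        sub, ins, dele = 0.6 * p.error, 0.2 * p.error, 0.2 * p.error
        mu = np.log(p.mean_len) - p.sigma**2 / 2
        for hap in genome.haplotypes:
            L = len(hap)
            n_reads = int(round(L * per_hap_depth / p.mean_len))
            if n_reads == 0:
                continue
            lengths = np.minimum(
                rng.lognormal(mu, p.sigma, n_reads).astype(int) + 1, L
            )
            starts = rng.integers(0, np.maximum(L - lengths, 1))
            for i in range(n_reads):
                s, rl = int(starts[i]), int(lengths[i])
                frag = hap.bases[s : s + rl]
                bases = _mutate_with_indels(frag, sub, ins, dele, rng)
                if rng.random() < 0.5:
                    bases = reverse_complement(bases)
                rid = f"{hap.id}:long:{s}:{i}"
                reads.append(SequencingRead(rid, bases, platform="long"))
                origins[rid] = (hap.id, s, s + rl)
    return ReadSimResult(reads=reads, origins=origins)


def write_fastq(reads: Sequence[SequencingRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "I" * len(r.bases)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# trio genotypes


@dataclass
class TrioSimResult:
    matrix: GenotypeMatrix
    trios: List[TrioSpec]
    true_genotypes: np.ndarray  # pre-error, no missingness
    site_freqs: np.ndarray
    hotspot_bins: Tuple[Tuple[str, int], ...]
    vcf_records: Optional[List[VariantRecord]] = None


def study_pedigree() -> List[TrioSpec]:
    """The study design: 12 trios, four families, groups of 6/3/3."""
    trios = []
    for i in range(1, 7):
        trios.append(TrioSpec("f1.sire", f"f1.dam{i}", f"f1.calf{i}", 1, "GH.H"))
    trios.append(TrioSpec("f2.sire", "f2.dam1", "f2.calf1", 2, "H.H"))
    for i in (1, 2):
        trios.append(TrioSpec("f3.sire", f"f3.dam{i}", f"f3.calf{i}", 3, "H.H"))
    for i in (1, 2, 3):
        trios.append(TrioSpec("f4.sire", f"f4.dam{i}", f"f4.calf{i}", 4, "Ho.H"))
    return trios


def _draw_freqs(spec: Tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec[0] == "uniform":
        return rng.uniform(spec[1], spec[2], n)
    if spec[0] == "point":
        return np.full(n, float(spec[1]))
    raise ValueError(f"unknown allele frequency distribution {spec!r}")


def _apply_genotype_error(
    g: np.ndarray, eps_site: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric single-step error channel, vectorized over sites x samples."""
    eps = eps_site[:, None]
    u = rng.random(g.shape)
    out = g.copy()
    het = g == 1
    out[het & (u < eps)] = 0
    out[het & (u >= eps) & (u < 2 * eps)] = 2
    hom0 = g == 0
    out[hom0 & (u < eps)] = 1
    out[hom0 & (u >= eps) & (u < eps + eps**2)] = 2
    hom2 = g == 2
    out[hom2 & (u < eps)] = 1
    out[hom2 & (u >= eps) & (u < eps + eps**2)] = 0
    return out


def simulate_trio_genotypes(
    cfg: SimulationConfig,
    trios: Optional[List[TrioSpec]] = None,
    with_vcf_info: bool = False,
) -> TrioSimResult:
    """HWE parents, Mendelian offspring, genotyping error and missingness.

    Error rates are boosted ``hotspot_boost``-fold inside configured hotspot
    bins. With ``with_vcf_info`` each site also receives INFO annotations
    drawn so that every hard-filter rule is exercised by a small fraction of
    records.
    """
    tp = cfg.trio
    if tp.n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(cfg.seed, "trios")
    trios = trios if trios is not None else study_pedigree()

    parents: List[str] = []
    offspring: List[str] = []
    for t in trios:
        for pid in (t.sire_id, t.dam_id):
            if pid not in parents:
                parents.append(pid)
        offspring.append(t.offspring_id)
    samples = parents + offspring

    n = tp.n_sites
    freqs = _draw_freqs(tp.freq, n, rng)
    positions = np.sort(
        rng.choice(tp.contig_length, size=n, replace=False)
    )
    family_of: Dict[str, int] = {}
    for t in trios:
        for sid in (t.sire_id, t.dam_id, t.offspring_id):
            family_of[sid] = t.family
    family_freqs: Dict[int, np.ndarray] = {}
    for fam in sorted({t.family for t in trios}):
        if tp.fst > 0:  # Balding-Nichols family-specific drift
            a = freqs * (1 - tp.fst) / tp.fst
            b = (1 - freqs) * (1 - tp.fst) / tp.fst
            family_freqs[fam] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        else:
            family_freqs[fam] = freqs
    true = np.zeros((n, len(samples)), dtype=np.int8)
    col = {s: i for i, s in enumerate(samples)}
    for pid in parents:
        f = family_freqs[family_of[pid]]
        u = rng.random(n)
        q = 1 - f
        g = np.where(u < q * q, 0, np.where(u < q * q + 2 * f * q, 1, 2))
        true[:, col[pid]] = g
    for t in trios:
        s = true[:, col[t.sire_id]].astype(float) / 2.0
        d = true[:, col[t.dam_id]].astype(float) / 2.0
        gam_s = (rng.random(n) < s).astype(np.int8)
        gam_d = (rng.random(n) < d).astype(np.int8)
        true[:, col[t.offspring_id]] = gam_s + gam_d

    eps_site = np.full(n, tp.eps)
    if tp.hotspot_bins:
        for contig, bin_start in tp.hotspot_bins:
            if contig != tp.contig:
                continue
            in_bin = (positions >= bin_start) & (positions < bin_start + tp.window)
            eps_site[in_bin] = np.minimum(tp.eps * tp.hotspot_boost, 0.45)
    observed = _apply_genotype_error(true, eps_site, rng)
    if tp.missing_rate > 0:
        miss = rng.random(observed.shape) < tp.missing_rate
        observed = observed.astype(np.int8)
        observed[miss] = -1

    sites = pd.DataFrame(
        {
            "contig": tp.contig,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    matrix = GenotypeMatrix(
        sites=sites, samples=samples, genotypes=observed.astype(np.int8)
    )

    vcf_records = None
    if with_vcf_info:
        vcf_records = []
        fail_frac = 0.02
        nominal = {
            "QD": (20.0, 5.0, 1.0),  # (mean, sd, failing value)
            "FS": (10.0, 5.0, 80.0),
            "SOR": (1.5, 0.5, 5.0),
            "ReadPosRankSum": (0.0, 1.0, -9.0),
            "DP": (600.0, 100.0, 4000.0),
            "MQ": (60.0, 2.0, 30.0),
            "MQRankSum": (0.0, 1.0, -13.0),
        }
        for i in range(n):
            info = {}
            for key, (mean, sd, bad) in nominal.items():
                if rng.random() < fail_frac:
                    info[key] = bad
                else:
                    info[key] = float(rng.normal(mean, sd))
            vcf_records.append(
                VariantRecord(
                    contig=tp.contig,
                    pos=int(positions[i]),
                    ref="A",
                    alts=("G",),
                    info=info,
                    genotypes=observed[i],
                )
            )

    return TrioSimResult(
        matrix=matrix,
        trios=trios,
        true_genotypes=true,
        site_freqs=freqs,
        hotspot_bins=tp.hotspot_bins,
        vcf_records=vcf_records,
    )


def plant_mendel_errors(
    matrix: GenotypeMatrix, trio: TrioSpec, site_indices: Sequence[int]
) -> int:
    """Force a Mendelian-inconsistent offspring genotype at chosen sites.

    Returns the number of sites actually changed (sites where a parent is
    missing are skipped). Used to create exact ground truth for the counter.
    """
    from .trio_mendel import CONSISTENT

    si = matrix.sample_index(trio.sire_id)
    di = matrix.sample_index(trio.dam_id)
    oi = matrix.sample_index(trio.offspring_id)
    planted = 0
    for idx in site_indices:
        s, d = matrix.genotypes[idx, si], matrix.genotypes[idx, di]
        if s < 0 or d < 0:
            continue
        for o in (0, 2, 1):
            if not CONSISTENT[s, d, o]:
                matrix.genotypes[idx, oi] = o
                planted += 1
                break
    return planted


# ---------------------------------------------------------------------------
# packaged fixture: the published per-trio error counts


def table1_fixture() -> List[MendelResult]:
    """The published 12-trio Mendelian error counts against the fixed
    14,084,653-variant denominator (no simulation involved)."""
    ref = resources.files("polledcheck.data") / "table1_mendel_counts.tsv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError("packaged trio-count fixture failed its checksum")
    df = pd.read_csv(ref.open("r"), sep="\t")
    results = []
    for _, row in df.iterrows():
        trio = TrioSpec(
            sire_id=str(row["sire"]),
            dam_id=str(row["dam"]),
            offspring_id=str(row["offspring"]),
            family=int(row["family"]),
            group=str(row["group"]),
        )
        results.append(
            MendelResult(
                trio=trio,
                n_errors=int(row["n_errors"]),
                n_sites_tested=TABLE1_DENOMINATOR,
            )
        )
    return results
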