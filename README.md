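# polledcheck

Verification analyses for genome-edited polled (hornless) cattle — the
computational checks a regulator or a lab would run to ask: *did the edit land
where intended, is anything else in the genome, and is it inherited normally?*

The package targets the introgression of the Celtic *POLLED* allele
(P<sub>C</sub>), in which a 212-bp repeat is duplicated in place of a 10-bp
segment (`CTGGTATTCT`) at the polled locus, and the known failure mode of
plasmid-templated homology-directed repair: integration of the donor-plasmid
backbone (~3.9 kb of pCR2.1) plus a second copy of the 1.6-kb HDR template
next to the intended edit (the P<sub>C</sub>\* allele). It is aimed at people
analysing whole-genome sequencing of edited founders and their offspring.

## What it computes

* **Allele models** (`locus_models`) — builds the p, P<sub>C</sub> and
  P<sub>C</sub>\* alleles from an edit specification and derives the
  *junction signatures*: the alignment-op patterns an error-free read spanning
  each allele junction produces against the unedited reference and against
  the amended reference (reference plus the intended insertion). Signature
  lengths (e.g. the deletion shown by reads crossing the repeat's 3' end) are
  emergent properties of the sequences, never hard-coded.
* **In-silico PCR** (`insilico_pcr`) — primer-site and amplicon prediction for
  the polled genotyping screen (horned product 389 bp, polled product
  389 + 202 = 591 bp; heterozygotes show both bands), plus the qPCR
  standard-curve efficiency *E* = 10^(−1/s) − 1 with its 90% validation gate.
* **Read baiting and classification** (`bait_classify`) — selects reads
  sharing ≥25 bp (one exact 25-mer) with the insertion sequence and assigns
  each to one of three expected classes: (A) pure match to the reference
  within the repeat or its 5' junction; (B) single alignment with a junction
  deletion at the repeat's 3' end; (C) split alignment on the reference but a
  pure match across the repeat–repeat junction of the amended reference.
  Anything else is reported UNEXPLAINED. Baited reads are also placed
  genome-wide and clustered to detect ectopic copies of the insertion.
* **Plasmid screen** (`plasmid_screen`) — per-base depth over the plasmid
  backbone (HDR insert masked) calls backbone presence from short reads;
  noisy long reads are assigned to P<sub>C</sub> vs P<sub>C</sub>\* by
  score margin at diagnostic junctions.
* **Variant QC** (`variant_qc`) — the GATK-style hard filters
  (QD < 2, FS > 60, SOR > 4, ReadPosRankSum < −8, DP > 3105; MQ < 40 and
  MQRankSum < −12.5 for SNPs; InbreedingCoeff < −0.8 for indels) and the
  cohort site filters (biallelic; genotype rate ≥ 95%; MAF ≥ 5%).
* **Trio Mendelian errors** (`trio_mendel`) — per-trio error counts and rates
  (% per variant and % per individual = per-variant/3), one-way ANOVA across
  study groups, a 10-kb windowed hotspot scan (bins with ≤10 total errors
  excluded; among the rest, bins with >1 error/kb in every group are
  "consistently high"), and an exact analytic expectation of the Mendelian
  error rate under a symmetric genotyping-error model.
* **IBS relatedness** (`ibs_phylo`) — PLINK-style VIF pruning (windows of 50
  SNPs, step 5, VIF ≤ 2), the 1 − IBS distance
  d(i,j) = 1 − Σ(2 − |g_i − g_j|) / 2M, and deterministic dendrograms
  (average linkage or neighbor joining) with Newick export.
* **Synthetic data** (`synthetic_data`) — seeded generators for all inputs
  (genomes with any locus genotype, 2×150-bp pairs at 20×, ~10-kb long reads
  at 14× and 10% error, 12-trio genotype matrices in three study groups of
  6/3/3) with full ground truth, plus a packaged fixture of the published
  per-trio error counts (denominator 14,084,653 variants).
* **Workbench** (`workbench`) — a `polledcheck` CLI with `simulate`,
  `integrity`, `trio-stats` (`--fixture-table1`) and `relatedness`
  subcommands producing versioned JSON run reports.

## Worked example

Published trio statistics from the packaged counts (no simulation):

```python
from polledcheck import run_trio_stats

report = run_trio_stats(fixture_table1=True)
stage = report.stages["table1"]
print(round(stage["mean_pct_per_variant"], 1))   # 1.0
print(round(stage["sd_pct_per_variant"], 1))     # 0.2
print(stage["anova"])  # F=3.431, p=0.078, df_between=2, df_within=9
```

The twelve per-trio per-variant percentages are
1.2, 1.1, 0.9, 1.0, 1.2, 1.0, 0.9, 0.9, 0.8, 1.0, 1.0, 1.3 — a mean error
rate of 1.0% per variant (SD 0.2) per meiosis, with no significant group
difference (F = 3.43, p = 0.078 on 2 and 9 df).

Edit-integrity screen on a simulated plasmid-carrier heterozygote
(P<sub>C</sub>\*p, error-free reads, 60-kb genome):

```python
from polledcheck import LocusParams, ShortReadParams, SimulationConfig, run_integrity

cfg = SimulationConfig(
    seed=7,
    locus=LocusParams(genome_length=60_000, locus_start=30_000, decoy_length=20_000),
    short=ShortReadParams(error=0.0),
)
report = run_integrity(cfg, animals={"bull": "Pc*p"})
print(report.stages["integrity:bull"]["class_counts"])
# {'A': 54, 'B': 0, 'C': 41, 'unexplained': 0}
print(report.stages["integrity:bull"]["ectopic_calls"])      # []
print(report.stages["integrity:bull"]["backbone_present"])   # True
```

Every baited read is explained by the three expected classes, no ectopic
insertion is found, and the backbone screen flags the plasmid carrier
(breadth 1.0). The same run on a plasmid-free animal reports
`backbone_present: False` with breadth ~0.

Or from the shell:

```bash
polledcheck trio-stats --fixture-table1 --out-dir out/
polledcheck integrity --seed 7 --genotype 'Pc*p' --out-dir out/
```

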