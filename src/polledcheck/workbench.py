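"""Report assembly and command-line interface.

Three analysis tracks tie the library stages together, each producing a
versioned, JSON-serializable run report:

* ``integrity`` — bait -> classify -> ectopic scan -> backbone screen ->
  long-read allele assignment on simulated genomes;
* ``trio-stats`` — site filters -> per-trio Mendelian errors -> group ANOVA
  -> windowed hotspot scan (or, with ``--fixture-table1``, the same
  statistics from the packaged published per-trio counts);
* ``relatedness`` — site filters -> VIF pruning -> 1-IBS distances ->
  dendrogram.

A ``simulate`` subcommand writes the simulated inputs to disk.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import click
import numpy as np
import yaml

from . import bait_classify as bc
from . import ibs_phylo as ip
from . import insilico_pcr  # noqa: F401  (re-exported surface)
from . import locus_models as lm
from . import plasmid_screen as ps
from . import synthetic_data as sd
from . import trio_mendel as tm
from . import variant_qc as vq

__version__ = "0.1.0"

SCHEMA_VERSION = 1

logger = logging.getLogger("polledcheck")


def _setup_logging(verbose: bool = True) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.INFO if verbose else logging.WARNING)


@dataclass
class RunReport:
    run_id: str
    seed: int
    config: dict
    stages: Dict[str, dict] = field(default_factory=dict)
    tool_version: str = __version__
    schema_version: int = SCHEMA_VERSION

    def add_stage(self, name: str, summary: dict) -> None:
        self.stages[name] = summary

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


class _Stage:
    """Context manager logging per-stage wall time at INFO."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        logger.info("stage %s finished in %.1f s", self.name, time.perf_counter() - self.t0)
        return False


def config_from_dict(d: dict, seed: Optional[int] = None) -> sd.SimulationConfig:
    return sd.SimulationConfig(
        seed=seed if seed is not None else int(d.get("seed", 1)),
        locus=sd.LocusParams(**d.get("locus", {})),
        short=sd.ShortReadParams(**d.get("short", {})),
        long=sd.LongReadParams(**d.get("long", {})),
        trio=sd.TrioParams(**{**d.get("trio", {}), **(
            {"hotspot_bins": tuple(tuple(b) for b in d["trio"]["hotspot_bins"])}
            if "hotspot_bins" in d.get("trio", {}) else {}
        )}),
    )


# ---------------------------------------------------------------------------
# analysis tracks


def run_integrity(
    cfg: sd.SimulationConfig,
    animals: Optional[Dict[str, str]] = None,
    plant_ectopic_in: Optional[str] = None,
    long_reads_for: Optional[str] = None,
    min_support: int = 3,
) -> RunReport:
    """Insertion-stability and plasmid-presence track on simulated data."""
    animals = animals or {"animal1": "Pcp"}
    report = RunReport(run_id=f"integrity-{cfg.seed}", seed=cfg.seed, config=_cfg_dict(cfg))

    with _Stage("simulate-genomes"):
        reference, genomes, truth = sd.make_genomes(cfg, animals, plant_ectopic_in)
    ref_locus = truth.ref_locus
    index = bc.build_bait_index([truth.repeat], k=25)
    genome_seqs = {name: seq.bases for name, seq in reference.items()}

    for sample, genome in genomes.items():
        # classify against the most amended allele this animal carries
        amended_name = "Pc_star" if "Pc*" in animals[sample] else "Pc"
        amended = truth.alleles[amended_name]
        signatures = lm.derive_junction_signatures(ref_locus, amended, cfg.short.read_len)
        with _Stage(f"short-reads:{sample}"):
            sim = sd.simulate_reads(genome, cfg, mode="short")
        with _Stage(f"bait-classify:{sample}"):
            baited = bc.bait_reads(sim.reads, index)
            rows = [
                (read, *bc.classify_read(read, ref_locus, amended.sequence, signatures))
                for read in baited
            ]
            counts = bc.class_counts(label for _, label, _ in rows)
        with _Stage(f"ectopic-scan:{sample}"):
            ectopic = bc.detect_ectopic_insertions(
                baited, genome_seqs, truth.expected_window, min_support=min_support
            )
        with _Stage(f"backbone-screen:{sample}"):
            screen = ps.screen_backbone(
                sim.reads, truth.backbone, sample_id=sample
            )
        report.add_stage(
            f"integrity:{sample}",
            {
                "genotype": animals[sample],
                "n_reads": len(sim.reads),
                "n_baited": len(baited),
                "class_counts": counts,
                "unexplained_ids": [
                    r.id for r, label, _ in rows if label == bc.ReadClassLabel.UNEXPLAINED
                ],
                "ectopic_calls": [
                    {
                        "contig": c.contig,
                        "window": [c.window_start, c.window_end],
                        "support": c.support,
                    }
                    for c in ectopic
                ],
                "backbone_breadth": screen.breadth,
                "backbone_present": screen.present,
            },
        )

    if long_reads_for is not None:
        sample = long_reads_for
        with _Stage(f"long-reads:{sample}"):
            sim = sd.simulate_reads(genomes[sample], cfg, mode="long")
            pc_model = lm.AlleleModel("Pc", truth.full_haplotypes["Pc"], [])
            star_model = lm.AlleleModel("Pc_star", truth.full_haplotypes["Pc_star"], [])
            assignments, support = ps.assign_long_reads(sim.reads, pc_model, star_model)
        report.add_stage(
            f"long-read-assignment:{sample}",
            {"n_long_reads": len(sim.reads), "support_counts": support},
        )
    return report


def run_trio_stats(
    cfg: Optional[sd.SimulationConfig] = None,
    fixture_table1: bool = False,
    apply_site_filters: bool = False,
) -> RunReport:
    """Mendelian-error track: per-trio rates, group ANOVA, hotspot scan."""
    seed = cfg.seed if cfg is not None else 0
    report = RunReport(
        run_id=f"trio-stats-{seed}",
        seed=seed,
        config=_cfg_dict(cfg) if cfg else {"fixture": "table1"},
    )
    if fixture_table1:
        results = sd.table1_fixture()
        table = tm.mendel_report(results)
        by_group: Dict[str, List[float]] = {}
        for r in results:
            by_group.setdefault(r.trio.group, []).append(r.pct_per_variant)
        anova = tm.oneway_anova(by_group, posthoc=True)
        pcts = [r.pct_per_variant for r in results]
        report.add_stage(
            "table1",
            {
                "rows": table.to_dict(orient="records"),
                "mean_pct_per_variant": float(np.mean(pcts)),
                "sd_pct_per_variant": float(np.std(pcts, ddof=1)),
                "anova": {
                    "F": anova.F,
                    "p": anova.p,
                    "df_between": anova.df_between,
                    "df_within": anova.df_within,
                },
            },
        )
        return report

    if cfg is None:
        raise ValueError("a simulation config is required without --fixture-table1")
    with _Stage("simulate-trios"):
        sim = sd.simulate_trio_genotypes(cfg)
    matrix = sim.matrix
    if apply_site_filters:
        matrix, excl = vq.site_filters(matrix)
        report.add_stage("site-filters", {"excluded": excl, "retained": matrix.n_sites})
    with _Stage("mendel"):
        results = [tm.count_trio_errors(matrix, t) for t in sim.trios]
    table = tm.mendel_report(results)
    by_group = {}
    for r in results:
        if r.pct_per_variant is not None:
            by_group.setdefault(r.trio.group, []).append(r.pct_per_variant)
    anova_summary: dict
    if all(r.n_errors == 0 for r in results):
        anova_summary = {"skipped": "no Mendelian errors observed"}
    else:
        a = tm.oneway_anova(by_group)
        anova_summary = {"F": a.F, "p": a.p, "df_between": a.df_between, "df_within": a.df_within}
    with _Stage("window-scan"):
        err_pos = {
            t.offspring_id: [
                (row.contig, int(row.pos))
                for row in matrix.sites[tm.mendel_error_mask(matrix, t)].itertuples()
            ]
            for t in sim.trios
        }
        groups = {t.offspring_id: t.group for t in sim.trios}
        _, error_prone, high = tm.window_error_scan(err_pos, groups, window=cfg.trio.window)
    report.add_stage(
        "trio-stats",
        {
            "rows": table.to_dict(orient="records"),
            "anova": anova_summary,
            "n_error_prone_bins": int(len(error_prone)),
            "n_consistently_high_bins": int(len(high)),
        },
    )
    return report


def run_relatedness(
    cfg: sd.SimulationConfig,
    prune: bool = True,
    method: str = "average_linkage",
) -> RunReport:
    """Relatedness track: filters -> VIF pruning -> 1-IBS -> dendrogram."""
    report = RunReport(run_id=f"relatedness-{cfg.seed}", seed=cfg.seed, config=_cfg_dict(cfg))
    with _Stage("simulate-trios"):
        sim = sd.simulate_trio_genotypes(cfg)
    if sim.matrix.n_samples < 2:
        raise ValueError("relatedness needs at least two samples")
    matrix, excl = vq.site_filters(sim.matrix)
    retained = matrix.n_sites
    if prune:
        with _Stage("vif-prune"):
            kept = ip.vif_prune(matrix)
            matrix = matrix.subset_sites(kept)
    with _Stage("ibs"):
        D = ip.ibs_distance(matrix)
        tree = ip.build_dendrogram(D, method=method)
    report.add_stage(
        "relatedness",
        {
            "site_filter_exclusions": excl,
            "sites_after_filters": retained,
            "sites_after_pruning": matrix.n_sites,
            "newick": tree.to_newick(),
            "method": method,
        },
    )
    return report


def _cfg_dict(cfg: Optional[sd.SimulationConfig]) -> dict:
    return asdict(cfg) if cfg is not None else {}


# ---------------------------------------------------------------------------
# CLI


def _load_cfg(config_path: Optional[str], seed: Optional[int]) -> sd.SimulationConfig:
    d = {}
    if config_path:
        d = yaml.safe_load(Path(config_path).read_text()) or {}
    return config_from_dict(d, seed=seed)


def _emit(report: RunReport, out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{report.run_id}.json"
    report.to_json(path)
    click.echo(str(path))


@click.group()
@click.option("--quiet", is_flag=True, help="suppress progress logging")
def main(quiet: bool):
    """Verification analyses for genome-edited polled cattle."""
    _setup_logging(verbose=not quiet)


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--out-dir", default="polledcheck_out", show_default=True)
@click.option("--genotype", default="Pcp", show_default=True)
def simulate(config_path, seed, out_dir, genotype):
    """Write a simulated reference, animal genome and reads to disk."""
    cfg = _load_cfg(config_path, seed)
    reference, genomes, truth = sd.make_genomes(cfg, {"animal1": genotype})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lm.write_fasta(reference.values(), out / "reference.fa")
    for sample, genome in genomes.items():
        lm.write_fasta(genome.haplotypes, out / f"{sample}.fa")
        sim = sd.simulate_reads(genome, cfg, mode="short")
        sd.write_fastq(sim.reads, out / f"{sample}.short.fastq")
    lm.write_features_bed(truth.alleles["Pc"], out / "pc_features.bed")
    click.echo(str(out))


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--out-dir", default="polledcheck_out", show_default=True)
@click.option("--genotype", default="Pcp", show_default=True)
@click.option("--long-reads/--no-long-reads", default=False)
def integrity(config_path, seed, out_dir, genotype, long_reads):
    """Insertion stability, ectopic scan and plasmid screen."""
    cfg = _load_cfg(config_path, seed)
    report = run_integrity(
        cfg,
        animals={"animal1": genotype},
        long_reads_for="animal1" if long_reads else None,
    )
    _emit(report, out_dir)


@main.command("trio-stats")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--out-dir", default="polledcheck_out", show_default=True)
@click.option("--fixture-table1", is_flag=True, help="use the packaged published counts")
def trio_stats(config_path, seed, out_dir, fixture_table1):
    """Per-trio Mendelian error rates, group ANOVA and hotspot scan."""
    cfg = None if fixture_table1 else _load_cfg(config_path, seed)
    report = run_trio_stats(cfg, fixture_table1=fixture_table1)
    _emit(report, out_dir)


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--out-dir", default="polledcheck_out", show_default=True)
@click.option("--no-prune", is_flag=True, help="skip VIF pruning")
@click.option(
    "--method",
    type=click.Choice(["average_linkage", "neighbor_joining"]),
    default="average_linkage",
    show_default=True,
)
def relatedness(config_path, seed, out_dir, no_prune, method):
    """VIF pruning, 1-IBS distances and dendrogram."""
    cfg = _load_cfg(config_path, seed)
    report = run_relatedness(cfg, prune=not no_prune, method=method)
    _emit(report, out_dir)


if __name__ == "__main__":
    main()
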