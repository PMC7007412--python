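"""Trio Mendelian-error counting, windowed hotspot scan and group ANOVA.

A Mendelian error is an offspring genotype at a biallelic site that cannot
be formed by one allele from each parent. Per-trio results report the error
count, the percentage per variant (100 * errors / sites tested, optionally
against a fixed denominator so published counts can be reproduced without
genotypes) and the percentage per individual (per-variant percentage divided
by the three trio members — the convention consistent with the published
per-trio rows). A 10-kb windowed scan flags error-prone genome intervals
(those with more than ten errors across all offspring) and, among them,
intervals whose per-group error rate exceeds 1 error per kb in every study
group. One-way ANOVA compares per-trio error percentages between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes (0/1/2, -1 = missing) at sites x samples."""

    sites: pd.DataFrame  # columns: contig, pos, ref, alt
    samples: List[str]
    genotypes: np.ndarray  # int8, shape (n_sites, n_samples)
    biallelic: Optional[np.ndarray] = None  # bool per site; None = all biallelic

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype array shape inconsistent with sites/samples")
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotypes must be 0, 1, 2 or -1 (missing)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def subset_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            genotypes=self.genotypes[idx],
            biallelic=None if self.biallelic is None else self.biallelic[idx],
        )


@dataclass(frozen=True)
class TrioSpec:
    sire_id: str
    dam_id: str
    offspring_id: str
    family: int
    group: str

    def __post_init__(self):
        if len({self.sire_id, self.dam_id, self.offspring_id}) != 3:
            raise ValueError("trio members must be three distinct samples")


@dataclass
class MendelResult:
    trio: TrioSpec
    n_errors: int
    n_sites_tested: int

    @property
    def pct_per_variant(self) -> Optional[float]:
        if self.n_sites_tested == 0:
            return None
        return 100.0 * self.n_errors / self.n_sites_tested

    @property
    def pct_per_individual(self) -> Optional[float]:
        pv = self.pct_per_variant
        return None if pv is None else pv / 3.0


# ---------------------------------------------------------------------------
# Mendelian consistency

def _consistency_table() -> np.ndarray:
    table = np.zeros((3, 3, 3), dtype=bool)
    gametes = {0: (0,), 1: (0, 1), 2: (1,)}
    for s in range(3):
        for d in range(3):
            possible = {a + b for a in gametes[s] for b in gametes[d]}
            for o in possible:
                table[s, d, o] = True
    return table


CONSISTENT = _consistency_table()


def is_mendelian_consistent(s: int, d: int, o: int) -> bool:
    """True iff offspring genotype o can receive one allele from each parent."""
    for g in (s, d, o):
        if g not in (0, 1, 2):
            raise ValueError(f"genotype {g} out of range (expected 0, 1 or 2)")
    return bool(CONSISTENT[s, d, o])


def count_trio_errors(
    matrix: GenotypeMatrix,
    trio: TrioSpec,
    skip_missing: bool = True,
    fixed_denominator: Optional[int] = None,
) -> MendelResult:
    """Count Mendelian-inconsistent sites for one trio.

    Sites with any missing genotype among the three members are skipped
    (neither errors nor tested). ``fixed_denominator`` replaces the tested
    count in the rate denominators (used to reproduce published rates that
    were computed against a fixed cohort-wide variant total).
    """
    si = matrix.sample_index(trio.sire_id)
    di = matrix.sample_index(trio.dam_id)
    oi = matrix.sample_index(trio.offspring_id)
    g = matrix.genotypes
    s, d, o = g[:, si], g[:, di], g[:, oi]
    called = (s != MISSING) & (d != MISSING) & (o != MISSING)
    if not skip_missing and not called.all():
        raise ValueError("missing genotypes present and skip_missing is False")
    errors = ~CONSISTENT[s[called], d[called], o[called]]
    n_tested = int(called.sum())
    return MendelResult(
        trio=trio,
        n_errors=int(errors.sum()),
        n_sites_tested=fixed_denominator if fixed_denominator is not None else n_tested,
    )


def mendel_error_mask(matrix: GenotypeMatrix, trio: TrioSpec) -> np.ndarray:
    """Boolean per-site mask of Mendelian errors for one trio (missing = False)."""
    si = matrix.sample_index(trio.sire_id)
    di = matrix.sample_index(trio.dam_id)
    oi = matrix.sample_index(trio.offspring_id)
    g = matrix.genotypes
    s, d, o = g[:, si], g[:, di], g[:, oi]
    called = (s != MISSING) & (d != MISSING) & (o != MISSING)
    mask = np.zeros(matrix.n_sites, dtype=bool)
    mask[called] = ~CONSISTENT[s[called], d[called], o[called]]
    return mask


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    group_means: Dict[str, float]
    posthoc: Optional[pd.DataFrame] = None


def oneway_anova(
    values_by_group: Dict[str, Sequence[float]], posthoc: bool = False
) -> AnovaResult:
    """One-way fixed-effects ANOVA across groups (optional Tukey HSD)."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group needs at least one value")
    if not any(len(v) >= 2 for v in groups.values()):
        raise ValueError("at least one group needs two or more values")
    arrays = list(groups.values())
    n_total = sum(len(v) for v in arrays)
    df_b = len(groups) - 1
    df_w = n_total - len(groups)
    grand = np.concatenate(arrays)
    ssb = sum(len(v) * (v.mean() - grand.mean()) ** 2 for v in arrays)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrays)
    if ssw == 0 and ssb == 0:
        warnings.warn("zero variance everywhere; F set to 0", stacklevel=2)
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*arrays)
    result = AnovaResult(
        F=float(F),
        p=float(p),
        df_between=df_b,
        df_within=df_w,
        group_means={k: float(v.mean()) for k, v in groups.items()},
    )
    if posthoc:
        res = stats.tukey_hsd(*arrays)
        names = list(groups)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "p": float(res.pvalue[i, j]),
                    }
                )
        result.posthoc = pd.DataFrame(rows)
    return result


# ---------------------------------------------------------------------------
# windowed error scan


@dataclass
class WindowErrorTable:
    """Per-bin Mendelian error counts (bins tile contigs in fixed windows)."""

    window: int
    table: pd.DataFrame  # index (contig, bin_start); one column per offspring
    group_of: Dict[str, str]

    def group_totals(self) -> pd.DataFrame:
        cols = {}
        for group in sorted(set(self.group_of.values())):
            members = [o for o, g in self.group_of.items() if g == group]
            cols[group] = self.table[members].sum(axis=1)
        return pd.DataFrame(cols)


def window_error_scan(
    error_positions: Dict[str, Sequence[Tuple[str, int]]],
    group_of: Dict[str, str],
    window: int = 10_000,
    min_total: int = 11,
    rate_per_kb: float = 1.0,
) -> Tuple[WindowErrorTable, pd.DataFrame, pd.DataFrame]:
    """Tile contigs into fixed windows, count errors and flag hotspots.

    Returns ``(table, error_prone_bins, consistently_high_bins)``: bins with
    total errors across all offspring >= ``min_total`` (i.e. the <= min_total-1
    exclusion applied) are error-prone; among those, bins where every study
    group's error rate exceeds ``rate_per_kb`` errors per kb are consistently
    high.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    counts: Dict[Tuple[str, int], Dict[str, int]] = {}
    for offspring, positions in error_positions.items():
        for contig, pos in positions:
            key = (contig, (pos // window) * window)
            counts.setdefault(key, {})
            counts[key][offspring] = counts[key].get(offspring, 0) + 1
    offspring_ids = sorted(error_positions)
    index = pd.MultiIndex.from_tuples(
        sorted(counts) or [], names=["contig", "bin_start"]
    )
    table = pd.DataFrame(
        [[counts[key].get(o, 0) for o in offspring_ids] for key in sorted(counts)],
        index=index,
        columns=offspring_ids,
        dtype=int,
    )
    wtable = WindowErrorTable(window=window, table=table, group_of=dict(group_of))
    totals = table.sum(axis=1) if len(table) else pd.Series(dtype=int)
    error_prone = table[totals >= min_total] if len(table) else table
    if len(error_prone):
        gt = WindowErrorTable(window, error_prone, dict(group_of)).group_totals()
        kb = window / 1000.0
        high = (gt / kb > rate_per_kb).all(axis=1)
        consistently_high = error_prone[high.values]
    else:
        consistently_high = error_prone
    return wtable, error_prone, consistently_high


# ---------------------------------------------------------------------------
# analytic expectation under the symmetric genotyping-error model


def genotype_error_matrix(eps: float) -> np.ndarray:
    """Symmetric single-step error channel over {0,1,2}.

    Neighbouring states are confused at rate eps, the two homozygotes at
    eps**2; rows sum to 1.
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must lie in [0, 1]")
    e = np.array(
        [
            [1 - eps - eps**2, eps, eps**2],
            [eps, 1 - 2 * eps, eps],
            [eps**2, eps, 1 - eps - eps**2],
        ]
    )
    if (e < 0).any():
        raise ValueError("eps too large for the single-step error model")
    return e


def _error_rate_at_freq(eps: float, p: float) -> float:
    q = 1 - p
    hwe = np.array([q * q, 2 * p * q, p * p])
    E = genotype_error_matrix(eps)
    total = 0.0
    for s in range(3):
        for d in range(3):
            # offspring distribution: one gamete per parent
            ps, pd_ = s / 2.0, d / 2.0
            off = np.array(
                [
                    (1 - ps) * (1 - pd_),
                    ps * (1 - pd_) + (1 - ps) * pd_,
                    ps * pd_,
                ]
            )
            prior = hwe[s] * hwe[d]
            for o in range(3):
                p_true = prior * off[o]
                if p_true == 0:
                    continue
                # observed triple through the error channel
                err = 0.0
                for so in range(3):
                    for do in range(3):
                        for oo in range(3):
                            if not CONSISTENT[so, do, oo]:
                                err += E[s, so] * E[d, do] * E[o, oo]
                total += p_true * err
    return total


def expected_error_rate(eps: float, allele_freq_dist) -> float:
    """Exact expected per-variant Mendelian error fraction.

    ``allele_freq_dist`` is ``("point", p)`` or ``("uniform", lo, hi)``; the
    uniform case integrates by Gauss-Legendre quadrature.
    """
    if eps == 0:
        return 0.0
    kind = allele_freq_dist[0]
    if kind == "point":
        return _error_rate_at_freq(eps, allele_freq_dist[1])
    if kind == "uniform":
        lo, hi = allele_freq_dist[1], allele_freq_dist[2]
        if not (0 <= lo < hi <= 1):
            raise ValueError("uniform bounds must satisfy 0 <= lo < hi <= 1")
        nodes, weights = np.polynomial.legendre.leggauss(24)
        x = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
        vals = np.array([_error_rate_at_freq(eps, p) for p in x])
        return float((weights * vals).sum() * 0.5)  # mean over the interval
    raise ValueError(f"unknown allele frequency distribution {allele_freq_dist!r}")


# ---------------------------------------------------------------------------
# I/O


def read_pedigree_tsv(path) -> List[TrioSpec]:
    """Trios from TSV with columns offspring, sire, dam, family, group."""
    df = pd.read_csv(path, sep="\t")
    return [
        TrioSpec(
            sire_id=str(r["sire"]),
            dam_id=str(r["dam"]),
            offspring_id=str(r["offspring"]),
            family=int(r["family"]),
            group=str(r["group"]),
        )
        for _, r in df.iterrows()
    ]


def read_matrix_tsv(path) -> GenotypeMatrix:
    """Genotype matrix from TSV: contig, pos, ref, alt, then sample columns."""
    df = pd.read_csv(path, sep="\t")
    meta = df[["contig", "pos", "ref", "alt"]]
    samples = [c for c in df.columns if c not in ("contig", "pos", "ref", "alt")]
    return GenotypeMatrix(
        sites=meta.reset_index(drop=True),
        samples=samples,
        genotypes=df[samples].to_numpy(dtype=np.int8),
    )


def write_matrix_tsv(matrix: GenotypeMatrix, path) -> None:
    df = matrix.sites.copy()
    for j, sample in enumerate(matrix.samples):
        df[sample] = matrix.genotypes[:, j]
    df.to_csv(path, sep="\t", index=False)


def mendel_report(results: Sequence[MendelResult]) -> pd.DataFrame:
    """Table-1-style report: one row per trio."""
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.trio.group,
                "family": r.trio.family,
                "sire": r.trio.sire_id,
                "dam": r.trio.dam_id,
                "offspring": r.trio.offspring_id,
                "n_errors": r.n_errors,
                "n_sites_tested": r.n_sites_tested,
                "pct_per_variant": np.nan if r.pct_per_variant is None else r.pct_per_variant,
                "pct_per_individual": np.nan
                if r.pct_per_individual is None
                else r.pct_per_individual,
            }
        )
    return pd.DataFrame(rows)
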