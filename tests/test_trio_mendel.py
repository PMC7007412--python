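"""Mendelian-error engine, ANOVA, window scan and the analytic error model."""

import itertools

import numpy as np
import pytest
from scipy import stats

from polledcheck import (
    SimulationConfig,
    TrioParams,
    TrioSpec,
    count_trio_errors,
    expected_error_rate,
    is_mendelian_consistent,
    oneway_anova,
    window_error_scan,
)
from polledcheck import synthetic_data as sd
from polledcheck.trio_mendel import mendel_error_mask, mendel_report

from conftest import matrix_from_array


def oracle_consistent(s, d, o):
    """Independent oracle: enumerate explicit parental allele pairs."""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    return any(
        a + b == o for a in alleles[s] for b in alleles[d]
    )


class TestConsistency:
    def test_trivial_triples(self):
        assert is_mendelian_consistent(0, 0, 0)
        assert not is_mendelian_consistent(0, 0, 2)

    def test_enumeration_of_27_combinations_matches_oracle(self):
        inconsistent = 0
        for s, d, o in itertools.product(range(3), repeat=3):
            assert is_mendelian_consistent(s, d, o) == oracle_consistent(s, d, o)
            inconsistent += not oracle_consistent(s, d, o)
        assert inconsistent == 12

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            is_mendelian_consistent(0, 3, 0)


class TestCountTrioErrors:
    TRIO = TrioSpec("sire", "dam", "kid", family=1, group="G")

    def test_published_row_rates_from_fixed_denominator(self):
        g = np.zeros((10, 3), dtype=np.int8)
        matrix = matrix_from_array(g, samples=["sire", "dam", "kid"])
        res = count_trio_errors(matrix, self.TRIO, fixed_denominator=14_084_653)
        res.n_errors = 169_672  # the published count for the first trio
        assert round(res.pct_per_variant, 1) == 1.2
        assert round(res.pct_per_individual, 1) == 0.4

    def test_all_missing_offspring_gives_na(self):
        g = np.zeros((5, 3), dtype=np.int8)
        g[:, 2] = -1
        matrix = matrix_from_array(g, samples=["sire", "dam", "kid"])
        res = count_trio_errors(matrix, self.TRIO)
        assert res.n_sites_tested == 0
        assert res.pct_per_variant is None and res.pct_per_individual is None
        assert np.isnan(mendel_report([res])["pct_per_variant"].iloc[0])

    def test_planted_errors_are_counted_exactly(self):
        cfg = SimulationConfig(seed=77, trio=TrioParams(n_sites=2000, eps=0.0, missing_rate=0.0))
        sim = sd.simulate_trio_genotypes(cfg)
        trio = sim.trios[0]
        base = count_trio_errors(sim.matrix, trio)
        assert base.n_errors == 0
        planted = sd.plant_mendel_errors(sim.matrix, trio, [10, 500, 1500])
        assert planted == 3
        assert count_trio_errors(sim.matrix, trio).n_errors == 3

    def test_invariance_to_site_order_and_parent_swap(self):
        cfg = SimulationConfig(seed=78, trio=TrioParams(n_sites=3000, eps=0.01))
        sim = sd.simulate_trio_genotypes(cfg)
        trio = sim.trios[3]
        res = count_trio_errors(sim.matrix, trio)
        perm = np.random.default_rng(0).permutation(sim.matrix.n_sites)
        res_perm = count_trio_errors(sim.matrix.subset_sites(perm), trio)
        swapped = TrioSpec(trio.dam_id, trio.sire_id, trio.offspring_id, trio.family, trio.group)
        res_swap = count_trio_errors(sim.matrix, swapped)
        assert res.n_errors == res_perm.n_errors == res_swap.n_errors

    def test_absent_member_raises(self):
        matrix = matrix_from_array(np.zeros((3, 3), dtype=np.int8), samples=["a", "b", "c"])
        with pytest.raises(KeyError):
            count_trio_errors(matrix, TrioSpec("a", "b", "ghost", 1, "G"))


class TestAnova:
    def test_identical_means_give_zero_f(self):
        res = oneway_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [2.0, 2.0, 2.0]})
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula_on_random_groups(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0.5, 1, 5),
            "c": rng.normal(-0.3, 1.2, 7),
        }
        res = oneway_anova(groups)
        # direct sum-of-squares evaluation
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        df_b, df_w = 2, len(allv) - 3
        F = (ssb / df_b) / (ssw / df_w)
        p = stats.f.sf(F, df_b, df_w)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert (res.df_between, res.df_within) == (df_b, df_w)

    def test_zero_variance_everywhere_warns(self):
        with pytest.warns(UserWarning):
            res = oneway_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert res.F == 0.0

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            oneway_anova({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            oneway_anova({"a": [1.0], "b": []})
        with pytest.raises(ValueError):
            oneway_anova({"a": [1.0], "b": [2.0]})


class TestWindowScan:
    def test_exclusion_boundary_at_ten_errors(self):
        positions_10 = {"kid": [("chr1", 5_000)] * 10}
        positions_11 = {"kid": [("chr1", 5_000)] * 11}
        groups = {"kid": "G"}
        _, prone10, _ = window_error_scan(positions_10, groups)
        _, prone11, _ = window_error_scan(positions_11, groups)
        assert len(prone10) == 0
        assert list(prone11.index) == [("chr1", 0)]

    def test_no_errors_no_bins(self):
        _, prone, high = window_error_scan({"kid": []}, {"kid": "G"})
        assert len(prone) == 0 and len(high) == 0

    def test_planted_hotspots_recovered_exactly(self):
        hotspots = (("chr1", 200_000), ("chr1", 740_000))
        cfg = SimulationConfig(
            seed=5,
            trio=TrioParams(
                n_sites=20_000,
                contig_length=1_000_000,
                eps=0.001,
                missing_rate=0.0,
                hotspot_bins=hotspots,
                hotspot_boost=50.0,
            ),
        )
        sim = sd.simulate_trio_genotypes(cfg)
        err_pos = {
            t.offspring_id: [
                (r.contig, int(r.pos))
                for r in sim.matrix.sites[mendel_error_mask(sim.matrix, t)].itertuples()
            ]
            for t in sim.trios
        }
        groups = {t.offspring_id: t.group for t in sim.trios}
        _, prone, high = window_error_scan(err_pos, groups)
        assert set(high.index) == set(hotspots)
        assert set(hotspots) <= set(prone.index)

    def test_bad_window_raises(self):
        with pytest.raises(ValueError):
            window_error_scan({"kid": []}, {"kid": "G"}, window=0)


class TestExpectedErrorRate:
    def test_zero_eps_gives_zero(self):
        assert expected_error_rate(0.0, ("uniform", 0.05, 0.95)) == 0.0

    def test_monotone_in_eps(self):
        rates = [
            expected_error_rate(e, ("uniform", 0.05, 0.95))
            for e in np.linspace(0.0, 0.1, 6)
        ]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_matches_monte_carlo_oracle(self):
        eps, n = 0.005, 1_000_000
        rng = np.random.default_rng(9)
        p = rng.uniform(0.05, 0.95, n)
        gs = rng.binomial(1, p, n) + rng.binomial(1, p, n)
        gd = rng.binomial(1, p, n) + rng.binomial(1, p, n)
        go = rng.binomial(1, gs / 2) + rng.binomial(1, gd / 2)

        def corrupt(g):
            u = rng.random(n)
            out = g.copy()
            het = g == 1
            out[het & (u < eps)] = 0
            out[het & (u >= eps) & (u < 2 * eps)] = 2
            for hom, near, far in ((0, 1, 2), (2, 1, 0)):
                m = g == hom
                out[m & (u < eps)] = near
                out[m & (u >= eps) & (u < eps + eps**2)] = far
            return out

        from polledcheck.trio_mendel import CONSISTENT

        os_, od_, oo_ = corrupt(gs), corrupt(gd), corrupt(go)
        mc = float((~CONSISTENT[os_, od_, oo_]).mean())
        analytic = expected_error_rate(eps, ("uniform", 0.05, 0.95))
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert abs(mc - analytic) < 3 * se

    def test_invalid_distribution_raises(self):
        with pytest.raises(ValueError):
            expected_error_rate(0.01, ("gamma", 1.0))
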