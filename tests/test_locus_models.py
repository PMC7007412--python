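"""Allele construction, diffing and junction signatures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polledcheck import (
    CelticEditSpec,
    NucSequence,
    PlasmidIntegrationSpec,
    apply_celtic_edit,
    build_plasmid_allele,
    derive_junction_signatures,
    diff_single_replacement,
    reverse_complement,
)
from polledcheck.locus_models import EditSpecError, read_fasta, write_fasta, write_features_bed

from conftest import random_locus


def _make_wild(rng, prefix_len, suffix_len, repeat_len=212, replaced="CTGGTATTCT"):
    prefix = random_locus(rng, prefix_len)
    repeat = random_locus(rng, repeat_len)
    suffix = random_locus(rng, suffix_len)
    wild = NucSequence("wild", prefix + repeat + replaced + suffix)
    spec = CelticEditSpec(
        repeat_start=prefix_len,
        repeat_end=prefix_len + repeat_len,
        replaced_start=prefix_len + repeat_len,
        replaced_end=prefix_len + repeat_len + len(replaced),
        replaced_seq=replaced,
    )
    return wild, spec, repeat


class TestCelticEdit:
    def test_flankless_locus_doubles_the_repeat(self):
        rng = np.random.default_rng(0)
        repeat = random_locus(rng, 212)
        wild = NucSequence("w", repeat + "CTGGTATTCT")
        spec = CelticEditSpec(0, 212, 212, 222)
        allele = apply_celtic_edit(wild, spec)
        assert len(allele) == 424
        assert allele.sequence.bases == repeat * 2

    def test_length_change_is_202(self):
        rng = np.random.default_rng(1)
        wild, spec, _ = _make_wild(rng, 500, 700)
        allele = apply_celtic_edit(wild, spec)
        assert len(allele) - len(wild) == 212 - 10 == 202

    def test_matches_string_concatenation_oracle(self):
        # spec at offsets (800, 1012, 1012, 1022) on a 2-kb locus
        rng = np.random.default_rng(2)
        wild, spec, repeat = _make_wild(rng, 800, 978)
        assert (spec.repeat_start, spec.repeat_end) == (800, 1012)
        allele = apply_celtic_edit(wild, spec)
        w = wild.bases
        oracle = w[:800] + repeat + repeat + w[1022:]
        assert allele.sequence.bases == oracle
        assert allele.feature("repeat_copy1") == ("repeat_copy1", 800, 1012)
        assert allele.feature("repeat_copy2") == ("repeat_copy2", 1012, 1224)

    def test_wild_type_mismatch_reports_offset(self):
        rng = np.random.default_rng(3)
        wild, _, _ = _make_wild(rng, 100, 100)
        bad = CelticEditSpec(100, 312, 312, 322, replaced_seq="AAAAAAAAAA")
        with pytest.raises(EditSpecError, match=r"offset 31\d"):
            apply_celtic_edit(wild, bad)

    def test_round_trip_diff_recovers_the_replacement(self):
        rng = np.random.default_rng(4)
        wild, spec, repeat = _make_wild(rng, 300, 400)
        allele = apply_celtic_edit(wild, spec)
        start, removed, inserted = diff_single_replacement(wild, allele.sequence)
        # homology can shift the minimal event, but it must be equivalent:
        # splicing the inserted piece back at the diff start reproduces Pc
        w = wild.bases
        assert w[:start] + inserted + w[start + len(removed):] == allele.sequence.bases
        assert len(inserted) - len(removed) == 202

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        repeat_len=st.integers(20, 300),
        replaced_len=st.integers(1, 30),
        prefix=st.integers(0, 200),
        suffix=st.integers(0, 200),
    )
    def test_length_arithmetic_property(self, seed, repeat_len, replaced_len, prefix, suffix):
        rng = np.random.default_rng(seed)
        wild, spec, _ = _make_wild(
            rng, prefix, suffix, repeat_len, random_locus(rng, replaced_len)
        )
        allele = apply_celtic_edit(wild, spec)
        assert len(allele) - len(wild) == spec.repeat_len - spec.replaced_len


class TestPlasmidAllele:
    @pytest.fixture()
    def pc(self):
        rng = np.random.default_rng(5)
        wild, spec, _ = _make_wild(rng, 995, 995)
        return apply_celtic_edit(wild, spec), rng

    def test_length_additivity(self, pc):
        allele, rng = pc
        assert len(allele) == 2414
        integ = PlasmidIntegrationSpec(
            backbone=NucSequence("bb", random_locus(rng, 3900)),
            hdr_template=NucSequence("hdr", random_locus(rng, 1600)),
            insertion_offset=allele.feature("repeat_copy2")[2],
        )
        star = build_plasmid_allele(allele, integ)
        assert len(star) == 7914
        assert star.feature("backbone")[2] - star.feature("backbone")[1] == 3900

    def test_reverse_orientation_reverse_complements_the_backbone(self, pc):
        allele, rng = pc
        bb = NucSequence("bb", random_locus(rng, 500))
        integ = PlasmidIntegrationSpec(
            backbone=bb,
            hdr_template=NucSequence("hdr", random_locus(rng, 200)),
            insertion_offset=100,
            orientation="reverse",
        )
        star = build_plasmid_allele(allele, integ)
        _, s, e = star.feature("backbone")
        assert star.sequence.bases[s:e] == reverse_complement(bb.bases)

    def test_out_of_bounds_offset_raises(self, pc):
        allele, rng = pc
        integ = PlasmidIntegrationSpec(
            backbone=NucSequence("bb", random_locus(rng, 100)),
            hdr_template=NucSequence("hdr", random_locus(rng, 100)),
            insertion_offset=len(allele) + 1,
        )
        with pytest.raises(IndexError):
            build_plasmid_allele(allele, integ)


class TestJunctionSignatures:
    def test_unedited_allele_has_no_signatures(self):
        rng = np.random.default_rng(6)
        wild, spec, _ = _make_wild(rng, 300, 300)
        from polledcheck import wild_allele

        assert derive_junction_signatures(wild, wild_allele(wild, spec), 150) == []

    def test_three_prime_junction_shows_an_emergent_deletion(self):
        rng = np.random.default_rng(7)
        wild, spec, _ = _make_wild(rng, 500, 500)
        allele = apply_celtic_edit(wild, spec)
        sigs = derive_junction_signatures(wild, allele, 150)
        del_sigs = [
            s
            for s in sigs
            if s.target == "reference"
            and any(op == "deletion" for op, _ in s.expected_pattern)
        ]
        assert del_sigs, "no deletion signature derived at the repeat 3' end"
        # the deletion length is emergent; for non-homologous synthetic
        # sequence it equals the replaced-segment length
        lengths = [
            n for s in del_sigs for op, n in s.expected_pattern if op == "deletion"
        ]
        assert spec.replaced_len in lengths
        # every variant junction also carries a pure-match amended signature
        assert any(s.target == "amended_reference" for s in sigs)


def test_fasta_round_trip_and_bed_export(tmp_path):
    rng = np.random.default_rng(8)
    wild, spec, _ = _make_wild(rng, 120, 60)
    allele = apply_celtic_edit(wild, spec)
    fa = tmp_path / "alleles.fa"
    write_fasta([wild, allele.sequence], fa)
    text = fa.read_text()
    assert all(len(line) <= 60 for line in text.splitlines() if not line.startswith(">"))
    back = read_fasta(fa)
    assert [s.bases for s in back] == [wild.bases, allele.sequence.bases]
    bed = tmp_path / "features.bed"
    write_features_bed(allele, bed)
    rows = [line.split("\t") for line in bed.read_text().splitlines()]
    assert [r[3] for r in rows] == ["repeat_copy1", "repeat_copy2"]
    assert all(int(r[1]) < int(r[2]) for r in rows)
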