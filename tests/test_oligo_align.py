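"""k-mer index, binding-site discovery and amplicon prediction."""

import dataclasses
import random

import pytest

from plexdesign import fixtures, thermo
from plexdesign.candidates import PrimerCandidate
from plexdesign.genome_io import GenomeReference, TargetRegion
from plexdesign.oligo_align import (BindingSite, build_oligo_index,
                                    find_binding_sites, predict_amplicons)
from plexdesign.params import DesignParameters
from plexdesign.thermo import ThermoConditions, reverse_complement

import oracles

COND = ThermoConditions()
PARAMS = DesignParameters()


def primer_at(seq, chrom="chr1", start=0, side="forward"):
    strand = "+" if side == "forward" else "-"
    return PrimerCandidate(side, seq, chrom, start, start + len(seq), strand,
                           60.0, 50.0)


def plant(genome_seq: str, motif: str, pos: int) -> str:
    return genome_seq[:pos] + motif + genome_seq[pos + len(motif):]


@pytest.fixture(scope="module")
def background():
    return fixtures.generate_genome(5, 5000, 0.5).chromosomes["chr1"]


class TestIndex:
    def test_plus_strand_postings(self):
        g = GenomeReference({"c": "ACGTACGT" + "A" * 1000})
        idx = build_oligo_index(g, 8)
        assert ("c", 0) in idx.lookup("ACGTACGT")

    def test_kmer_spanning_n_absent(self):
        g = GenomeReference({"c": "ACGTACGTNACGTACG" + "T" * 1000})
        idx = build_oligo_index(g, 8)
        for kmer in idx.postings:
            assert "N" not in kmer

    def test_k_out_of_range(self):
        g = GenomeReference({"c": "A" * 1000})
        with pytest.raises(ValueError):
            build_oligo_index(g, 7)


class TestFindBindingSites:
    def test_unique_planted_motif_found_once(self, background):
        rng = random.Random(1)
        motif = "".join(rng.choice("ACGT") for _ in range(20))
        g = GenomeReference({"chr1": plant(background, motif, 2000)})
        idx = build_oligo_index(g, PARAMS.seed_k)
        sites = find_binding_sites(primer_at(motif, start=2000), idx, g,
                                   PARAMS, COND)
        assert [(s.site_start, s.strand, s.mismatches, s.is_intended)
                for s in sites] == [(2000, "+", 0, True)]

    def test_reverse_strand_motif_found(self, background):
        rng = random.Random(2)
        motif = "".join(rng.choice("ACGT") for _ in range(20))
        g = GenomeReference({"chr1": plant(background,
                                           reverse_complement(motif), 3000)})
        idx = build_oligo_index(g, PARAMS.seed_k)
        sites = find_binding_sites(primer_at(motif), idx, g, PARAMS, COND)
        assert any(s.strand == "-" and s.site_start == 3000 for s in sites)

    def test_nine_mismatch_copy_not_reported(self, background):
        rng = random.Random(3)
        motif = "".join(rng.choice("ACGT") for _ in range(25))
        decoy = list(motif)
        for p in rng.sample(range(25), 9):
            decoy[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[decoy[p]]
        g = GenomeReference({"chr1": plant(plant(background, motif, 1000),
                                           "".join(decoy), 3000)})
        idx = build_oligo_index(g, PARAMS.seed_k)
        sites = find_binding_sites(primer_at(motif, start=1000), idx, g,
                                   PARAMS, COND)
        assert all(s.site_start != 3000 for s in sites)

    def test_matches_exhaustive_scan_with_5prime_mutated_plants(self, background):
        rng = random.Random(4)
        for trial in range(10):
            primer = "".join(rng.choice("ACGT") for _ in range(rng.randint(18, 25)))
            seq = background
            pos = 1000
            for m in (0, 1, 2, 3):
                copy = list(primer)
                for p in rng.sample(range(6), m):   # 5' region mutations
                    copy[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[p]]
                seq = plant(seq, "".join(copy), pos)
                pos += 400
            g = GenomeReference({"chr1": seq})
            idx = build_oligo_index(g, PARAMS.seed_k)
            mine = find_binding_sites(primer_at(primer, start=1000), idx, g,
                                      PARAMS, COND)
            ref = oracles.scan_binding_sites(primer, g, PARAMS, COND,
                                             intended=("chr1", "+", 1000))
            assert [(s.chrom, s.strand, s.site_start, s.mismatches, s.dg_kcal_mol)
                    for s in mine] == \
                   [(s.chrom, s.strand, s.site_start, s.mismatches, s.dg_kcal_mol)
                    for s in ref]

    def test_threshold_relaxation_is_monotone(self, background):
        rng = random.Random(6)
        primer = "".join(rng.choice("ACGT") for _ in range(22))
        copy = list(primer)
        for p in rng.sample(range(5), 2):
            copy[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[p]]
        g = GenomeReference({"chr1": plant(plant(background, primer, 1000),
                                           "".join(copy), 3200)})
        idx = build_oligo_index(g, PARAMS.seed_k)
        tight = dataclasses.replace(PARAMS, max_mismatches=0,
                                    dg_threshold_kcal=-18.0)
        loose = PARAMS
        sites_tight = find_binding_sites(primer_at(primer, start=1000), idx, g,
                                         tight, COND)
        sites_loose = find_binding_sites(primer_at(primer, start=1000), idx, g,
                                         loose, COND)
        key = lambda ss: {(s.strand, s.site_start) for s in ss}
        assert key(sites_tight) <= key(sites_loose)

    def test_strand_symmetry_under_genome_mirror(self, background):
        rng = random.Random(7)
        primer = "".join(rng.choice("ACGT") for _ in range(20))
        g = GenomeReference({"chr1": plant(background, primer, 2500)})
        gm = GenomeReference({"chr1": reverse_complement(g.chromosomes["chr1"])})
        n = len(background)
        idx, idxm = build_oligo_index(g, 12), build_oligo_index(gm, 12)
        sites = find_binding_sites(primer_at(primer), idx, g, PARAMS, COND)
        mirror = find_binding_sites(primer_at(primer), idxm, gm, PARAMS, COND)
        flipped = {("-" if s.strand == "+" else "+", n - s.site_end)
                   for s in sites}
        assert flipped == {(s.strand, s.site_start) for s in mirror}


def _site(strand, start, end, intended=False):
    return BindingSite("chr1", strand, start, end, end - start, 0, 0, -15.0,
                       intended)


class TestPredictAmplicons:
    targets = [TargetRegion("chr1", 1200, 1202, "t1")]

    def test_intended_fr_amplicon_on_target(self):
        f = [_site("+", 1000, 1020, True)]
        r = [_site("-", 1360, 1380, True)]
        amps = predict_amplicons(f, r, PARAMS, self.targets, own_target_ids={"t1"})
        assert len(amps) == 1
        a = amps[0]
        assert (a.orientation, a.span, a.on_target) == ("FR", 380, True)
        assert a.covered_target_ids == ("t1",)

    def test_parallel_sites_give_no_amplicon(self):
        f = [_site("+", 1000, 1020), _site("+", 1300, 1320)]
        amps = predict_amplicons(f, [], PARAMS, self.targets)
        assert amps == []

    def test_ff_off_target_amplicon(self):
        f = [_site("+", 3000, 3020), _site("-", 3280, 3300)]
        amps = predict_amplicons(f, [], PARAMS, self.targets)
        assert len(amps) == 1
        assert amps[0].orientation == "FF"
        assert not amps[0].on_target

    def test_span_cutoff(self):
        f = [_site("+", 1000, 1020, True)]
        r = [_site("-", 1590, 1610, True)]
        assert predict_amplicons(f, r, PARAMS, self.targets,
                                 own_target_ids={"t1"}) == []
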