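"""Candidate pair enumeration, ranking and 5' tag attachment."""

import dataclasses

import pytest

from plexdesign import fixtures
from plexdesign.candidates import attach_tags, enumerate_candidate_pairs
from plexdesign.genome_io import TargetRegion, extract_design_window
from plexdesign.params import (DEFAULT_TAG_FORWARD, DEFAULT_TAG_REVERSE,
                               DesignParameters, FailureRecord)
from plexdesign.thermo import ThermoConditions, duplex_tm, reverse_complement

COND = ThermoConditions()


@pytest.fixture(scope="module")
def designable():
    """A synthetic locus with engineered primer islands and its window."""
    sc = fixtures.build_scenario("unique_panel")
    target = sc.targets[0]
    window = extract_design_window(sc.genome, target, sc.params.product_max)
    return sc, target, window


class TestEnumerate:
    def test_pairs_contain_target_and_respect_bounds(self, designable):
        sc, target, window = designable
        pairs = enumerate_candidate_pairs(window, sc.params, COND)
        assert pairs and not isinstance(pairs, FailureRecord)
        for p in pairs:
            assert p.product_start <= target.start and target.end <= p.product_end
            assert sc.params.product_min <= p.product_length <= sc.params.product_max
            for c in (p.forward, p.reverse):
                assert sc.params.primer_len_min <= c.length <= sc.params.primer_len_max
                assert sc.params.tm_min <= c.tm_C <= sc.params.tm_max
                assert sc.params.gc_min <= c.gc_percent <= sc.params.gc_max

    def test_sequences_match_genome(self, designable):
        sc, _, window = designable
        pairs = enumerate_candidate_pairs(window, sc.params, COND)
        for p in pairs[:5]:
            f, r = p.forward, p.reverse
            assert f.sequence == sc.genome.fetch(f.chrom, f.genome_start, f.genome_end)
            assert r.sequence == reverse_complement(
                sc.genome.fetch(r.chrom, r.genome_start, r.genome_end))
            assert f.tm_C == pytest.approx(duplex_tm(f.sequence, COND))

    def test_ranked_by_penalty_deterministically(self, designable):
        sc, _, window = designable
        pairs = enumerate_candidate_pairs(window, sc.params, COND)
        penalties = [p.penalty for p in pairs]
        assert penalties == sorted(penalties)
        again = enumerate_candidate_pairs(window, sc.params, COND)
        assert [p.pair_id for p in again] == [p.pair_id for p in pairs]
        assert [p.forward.genome_start for p in again] == \
               [p.forward.genome_start for p in pairs]

    def test_truncated_to_n_candidates(self, designable):
        sc, _, window = designable
        params = dataclasses.replace(sc.params, n_candidates_per_target=2)
        pairs = enumerate_candidate_pairs(window, params, COND)
        assert len(pairs) == 2

    def test_overlong_target_fails_on_product_size(self):
        # a 450 bp target with a 400 bp product cap: primers design fine on
        # both flanks but the left/right sets cannot be matched by length
        genome = fixtures.generate_genome(77, 6000, 0.5)
        params = DesignParameters(product_min=100, product_max=400)
        t = TargetRegion("chr1", 2000, 2450, "oversized")
        window = extract_design_window(genome, t, params.product_max)
        result = enumerate_candidate_pairs(window, params, COND)
        assert isinstance(result, FailureRecord)
        assert result.stage == "design"
        assert result.reason == "product size"
        assert result.detail["left_primers"] > 0
        assert result.detail["right_primers"] > 0

    def test_window_too_small(self):
        sc = fixtures.build_scenario("unique_panel")
        chrom = next(iter(sc.genome.chromosomes))
        t = TargetRegion(chrom, 2, 4, "edge")
        window = extract_design_window(sc.genome, t, 5)
        result = enumerate_candidate_pairs(window, sc.params, COND)
        assert isinstance(result, FailureRecord)
        assert result.stage == "design"


class TestAttachTags:
    def test_default_tag_lengths(self, designable):
        sc, _, window = designable
        pair = enumerate_candidate_pairs(window, sc.params, COND)[0]
        tagged = attach_tags(pair, DEFAULT_TAG_FORWARD, DEFAULT_TAG_REVERSE)
        assert len(tagged.tagged_forward) == 34 + pair.forward.length
        assert len(tagged.tagged_reverse) == 33 + pair.reverse.length
        assert tagged.tagged_forward.endswith(pair.forward.sequence)
        assert tagged.forward.sequence == pair.forward.sequence

    def test_empty_tags_are_identity(self, designable):
        sc, _, window = designable
        pair = enumerate_candidate_pairs(window, sc.params, COND)[0]
        tagged = attach_tags(pair, "", "")
        assert tagged.tagged_forward == pair.forward.sequence
        assert tagged.tagged_reverse == pair.reverse.sequence

    def test_non_acgt_tag_rejected(self, designable):
        sc, _, window = designable
        pair = enumerate_candidate_pairs(window, sc.params, COND)[0]
        with pytest.raises(ValueError):
            attach_tags(pair, "GTCN", "")
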