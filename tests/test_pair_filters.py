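"""Single-pair filters: boundary semantics, mask windows, specificity,
order-invariance of the kept set."""

import dataclasses
import itertools

import pytest

from plexdesign import pair_filters, thermo
from plexdesign.genome_io import MaskTrack
from plexdesign.oligo_align import build_oligo_index
from plexdesign.pair_filters import (apply_single_pair_filters, dimer_filter,
                                     hairpin_filter, mask_filter,
                                     specificity_filter)
from plexdesign.params import DesignParameters
from plexdesign.thermo import ThermoConditions, ThermoResult

from intervaltree import IntervalTree

COND = ThermoConditions()
PARAMS = DesignParameters()


@pytest.fixture(scope="module")
def clean_pair(run_scenario):
    sc, rep = run_scenario("unique_panel")
    return sc, next(iter(rep.cluster.members.values()))


class TestThresholdBoundaries:
    """The thresholds are strict: Tm exactly at 45 / 40 C passes."""

    @pytest.mark.parametrize("tm,kept", [(44.99, True), (45.0, True),
                                         (45.01, False), (60.0, False)])
    def test_hairpin_strictly_over(self, monkeypatch, clean_pair, tm, kept):
        _, pair = clean_pair
        monkeypatch.setattr(pair_filters.thermo, "hairpin_eval",
                            lambda *a, **k: ThermoResult(True, tm, -5.0, "stub"))
        verdict = hairpin_filter(pair, PARAMS, COND)
        assert verdict.kept is kept
        if not kept:
            assert verdict.stage == "hairpin"
            assert verdict.metrics["tm_C"] == tm

    @pytest.mark.parametrize("tm,kept", [(39.9, True), (40.0, True),
                                         (40.01, False)])
    def test_dimer_strictly_over(self, monkeypatch, clean_pair, tm, kept):
        _, pair = clean_pair
        monkeypatch.setattr(pair_filters.thermo, "heterodimer_eval",
                            lambda *a, **k: ThermoResult(True, tm, -5.0, "stub"))
        assert dimer_filter(pair, PARAMS, COND).kept is kept


class TestStructureFilters:
    def test_engineered_hairpin_dropped(self, run_scenario):
        sc, rep = run_scenario("hairpin_trap")
        recs = [f for f in rep.failures if f.pair_id == "t_hp-1"]
        assert recs and recs[0].stage == "hairpin"
        assert recs[0].detail["tm_C"] > PARAMS.hairpin_tm_threshold

    def test_reverse_complement_pair_dropped_as_dimer(self, run_scenario):
        sc, rep = run_scenario("dimer_trap")
        recs = [f for f in rep.failures if f.pair_id == "t_dim-1"]
        assert recs and recs[0].stage == "dimer"
        assert recs[0].detail["tm_C"] > PARAMS.dimer_tm_threshold

    def test_clean_tagged_pair_kept(self, clean_pair):
        _, pair = clean_pair
        assert hairpin_filter(pair, PARAMS, COND).kept
        assert dimer_filter(pair, PARAMS, COND).kept


class TestMaskFilter:
    def _mask_at(self, chrom, start, end, kind):
        track = MaskTrack()
        tree = IntervalTree()
        tree.addi(start, end)
        getattr(track, kind)[chrom] = tree
        return track

    def test_site_under_3prime_base_drops(self, clean_pair):
        _, pair = clean_pair
        pos = pair.forward.genome_end - 1
        track = self._mask_at(pair.chrom, pos, pos + 1, "sites")
        v = mask_filter(pair, track, PARAMS)
        assert not v.kept and v.stage == "masked_site"

    def test_site_outside_7bp_window_kept(self, clean_pair):
        _, pair = clean_pair
        pos = pair.forward.genome_end - 1 - PARAMS.three_prime_mask_window
        track = self._mask_at(pair.chrom, pos, pos + 1, "sites")
        assert mask_filter(pair, track, PARAMS).kept

    def test_area_under_5prime_half_kept(self, clean_pair):
        _, pair = clean_pair
        s = pair.forward.genome_start
        track = self._mask_at(pair.chrom, s, s + 3, "areas")
        assert mask_filter(pair, track, PARAMS).kept

    def test_reverse_primer_3prime_is_left_end(self, clean_pair):
        _, pair = clean_pair
        pos = pair.reverse.genome_start
        track = self._mask_at(pair.chrom, pos, pos + 1, "areas")
        v = mask_filter(pair, track, PARAMS)
        assert not v.kept and v.stage == "masked_area"


class TestSpecificity:
    def test_duplicated_amplicon_dropped(self, run_scenario):
        sc, rep = run_scenario("decoy_duplicate")
        recs = [f for f in rep.failures if f.pair_id == "t_dup-1"]
        assert recs and recs[0].stage == "specificity"
        assert recs[0].detail["off_target_amplicons"] >= 1

    def test_heavily_mutated_decoy_kept(self, run_scenario):
        sc, rep = run_scenario("decoy_duplicate")
        assert rep.outcomes["t_weak"] == "clustered"

    def test_unique_pair_kept_and_sites_cached(self, clean_pair):
        sc, pair = clean_pair
        index = build_oligo_index(sc.genome, sc.params.seed_k)
        v = specificity_filter(pair, index, sc.genome, sc.params, COND, sc.targets)
        assert v.kept
        assert pair.forward_sites is not None
        assert sum(s.is_intended for s in pair.forward_sites) == 1


class TestComposedStage:
    def test_kept_set_invariant_under_filter_order(self, scenario):
        sc = scenario("decoy_duplicate")
        from plexdesign.candidates import attach_tags, enumerate_candidate_pairs
        from plexdesign.genome_io import extract_design_window
        index = build_oligo_index(sc.genome, sc.params.seed_k)
        kept_ids = []
        for order in itertools.permutations(("hairpin", "dimer", "mask",
                                             "specificity")):
            pairs = {}
            for t in sc.targets:
                w = extract_design_window(sc.genome, t, sc.params.product_max)
                pairs[t.target_id] = [attach_tags(p, "", "") for p in
                                      enumerate_candidate_pairs(w, sc.params, COND)]
            kept, _ = apply_single_pair_filters(pairs, sc.masks, index,
                                                sc.genome, sc.params, COND,
                                                sc.targets, order=order)
            kept_ids.append({tid: [p.pair_id for p in ps]
                             for tid, ps in kept.items()})
        assert all(k == kept_ids[0] for k in kept_ids)

    def test_first_failure_stage_attribution_partitions(self, run_scenario):
        _, rep = run_scenario("masked_3prime")
        per_pair = [f for f in rep.failures if f.pair_id is not None]
        assert len(per_pair) == len({f.pair_id for f in per_pair})
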