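"""Compatibility, greedy seeding, relaxation, overlap collapse, brute force."""

import dataclasses

import pytest

from plexdesign import clustering, fixtures
from plexdesign.clustering import (brute_force_cluster,
                                   cross_pair_incompatibility,
                                   count_nonspecific_sites, collapse_overlaps,
                                   greedy_seed_cluster, pair_unity,
                                   relax_cluster)
from plexdesign.params import DesignParameters
from plexdesign.thermo import ThermoConditions

COND = ThermoConditions()
PARAMS = DesignParameters()


def make_pair(tm_f=60.0, tm_r=60.0, product=260, **kw):
    cands, _ = fixtures.random_cluster_instance(1, m=1, n=1, uniform_k=0)
    pair = cands["s00"][0]
    fwd = dataclasses.replace(pair.forward, tm_C=tm_f)
    rev = dataclasses.replace(pair.reverse, tm_C=tm_r,
                              genome_start=pair.forward.genome_start + product - 20,
                              genome_end=pair.forward.genome_start + product)
    new = dataclasses.replace(pair, forward=fwd, reverse=rev, **kw)
    new.forward_sites, new.reverse_sites = pair.forward_sites, pair.reverse_sites
    return new


class TestUnity:
    @pytest.mark.parametrize("p_a,p_b,tm_a,tm_b,expect", [
        (200, 349, 60.0, 60.0, True),    # 149 < 150
        (200, 350, 60.0, 60.0, False),   # 150 not < 150
        (260, 260, 60.0, 64.9, True),    # 4.9 < 5
        (260, 260, 60.0, 65.0, False),
    ])
    def test_strict_boundaries(self, p_a, p_b, tm_a, tm_b, expect):
        a = make_pair(tm_f=tm_a, tm_r=tm_a, product=p_a)
        b = make_pair(tm_f=tm_b, tm_r=tm_b, product=p_b)
        assert pair_unity(a, b, PARAMS) is expect


class TestCrossIncompatibility:
    def test_planted_cross_trap_counts_one(self, run_scenario):
        sc, rep = run_scenario("cross_pair_trap")
        kept = rep.kept_by_target
        pa, pb = kept["t_a"][0], kept["t_b"][0]
        v0 = cross_pair_incompatibility(pa, pb, sc.params, COND, sc.targets,
                                        budget=0)
        assert not v0.compatible
        assert v0.cross_false_amplicon_count == 1
        v1 = cross_pair_incompatibility(pa, pb, sc.params, COND, sc.targets,
                                        budget=1)
        assert v1.compatible

    def test_disjoint_clean_pairs_compatible(self, run_scenario):
        sc, rep = run_scenario("unique_panel")
        members = list(rep.cluster.members.values())
        v = cross_pair_incompatibility(members[0], members[1], sc.params,
                                       COND, sc.targets, budget=0)
        assert v.compatible and v.cross_false_amplicon_count == 0

    def test_reverse_complement_primers_cross_dimerise(self):
        from plexdesign import thermo
        a = make_pair()
        b = make_pair()
        b.tagged_reverse = thermo.reverse_complement(a.tagged_forward)
        v = cross_pair_incompatibility(a, b, PARAMS, COND, [], budget=0)
        assert any(x["kind"] == "cross_dimer" for x in v.violations)


class TestCountNonspecific:
    def test_intended_only_is_zero(self):
        cands, _ = fixtures.random_cluster_instance(3, m=1, n=1, uniform_k=0)
        assert count_nonspecific_sites(cands["s00"][0]) == 0

    def test_fabricated_counts_add_up(self):
        cands, _ = fixtures.random_cluster_instance(3, m=1, n=1, uniform_k=2)
        assert count_nonspecific_sites(cands["s00"][0]) == 4


class TestGreedyContract:
    def _check_valid_and_maximal(self, cands, targets, cluster):
        members = list(cluster.members.values())
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                assert cross_pair_incompatibility(
                    a, b, PARAMS, COND, targets, budget=0).compatible
        for rec in cluster.uncovered:
            for cand in cands[rec.target_id]:
                addable = all(cross_pair_incompatibility(
                    cand, m, PARAMS, COND, targets, budget=0).compatible
                    for m in members)
                assert not addable

    @pytest.mark.parametrize("seed", range(12))
    def test_valid_maximal_and_dominated_by_optimum(self, seed):
        rng_m = 3 + seed % 5
        cands, targets = fixtures.random_cluster_instance(100 + seed, m=rng_m, n=2)
        greedy = greedy_seed_cluster(cands, PARAMS, COND, targets)
        self._check_valid_and_maximal(cands, targets, greedy)
        optimal, _ = brute_force_cluster(cands, PARAMS, COND, targets)
        assert len(optimal.members) >= len(greedy.members)

    def test_single_conflict_resolved_by_site_count(self, run_scenario):
        sc, _ = run_scenario("cross_pair_trap")
        # both pairs have one nonspecific site; ties break deterministically
        kept = {"t_a": [], "t_b": []}
        _, rep = run_scenario("cross_pair_trap")
        kept = rep.kept_by_target
        cluster = greedy_seed_cluster(kept, sc.params, COND, sc.targets)
        assert len(cluster.members) == 1
        assert len(cluster.uncovered) == 1

    def test_empty_input_empty_cluster(self):
        cluster = greedy_seed_cluster({}, PARAMS, COND, [])
        assert cluster.members == {} and cluster.uncovered == []

    def test_deterministic(self):
        cands, targets = fixtures.random_cluster_instance(7, m=6, n=3)
        a = greedy_seed_cluster(cands, PARAMS, COND, targets)
        b = greedy_seed_cluster(cands, PARAMS, COND, targets)
        assert a.seed_order == b.seed_order


class TestRelaxation:
    def test_budget_ladder_admits_planted_counts(self, scenario):
        sc = scenario("relaxation_ladder")
        from plexdesign import pair_filters
        from plexdesign.candidates import attach_tags, enumerate_candidate_pairs
        from plexdesign.genome_io import extract_design_window
        from plexdesign.oligo_align import build_oligo_index
        pairs = {}
        for t in sc.targets:
            w = extract_design_window(sc.genome, t, sc.params.product_max)
            pairs[t.target_id] = [attach_tags(p, "", "") for p in
                                  enumerate_candidate_pairs(w, sc.params, COND)]
        index = build_oligo_index(sc.genome, sc.params.seed_k)
        kept, _ = pair_filters.apply_single_pair_filters(
            pairs, sc.masks, index, sc.genome, sc.params, COND, sc.targets)
        greedy = greedy_seed_cluster(kept, sc.params, COND, sc.targets)
        leftovers = {r.target_id: kept.get(r.target_id, [])
                     for r in greedy.uncovered}
        covered = {}
        admitted = {}
        for b in range(5):
            relaxed = relax_cluster(greedy, leftovers, b, sc.params, COND,
                                    sc.targets)
            covered[b] = len(relaxed.members)
            admitted[b] = set(relaxed.members) - set(greedy.members)
        assert covered == sc.truth["covered_by_budget"]
        # monotone in budget, members never evicted
        for b in range(1, 5):
            assert admitted[b - 1] <= admitted[b]

    def test_budget_zero_is_noop_on_maximal_cluster(self):
        cands, targets = fixtures.random_cluster_instance(42, m=5, n=2)
        greedy = greedy_seed_cluster(cands, PARAMS, COND, targets)
        leftovers = {r.target_id: cands[r.target_id] for r in greedy.uncovered}
        relaxed = relax_cluster(greedy, leftovers, 0, PARAMS, COND, targets)
        assert set(relaxed.members) == set(greedy.members)


class TestCollapse:
    def test_tiled_targets_collapse_to_one_amplicon(self, run_scenario):
        sc, rep = run_scenario("overlap_cluster")
        assert len(rep.cluster.members) == 1
        (pid, covered), = rep.overlap.amplicon_to_targets.items()
        assert sorted(covered) == sorted(t.target_id for t in sc.targets)

    def test_disjoint_targets_identity(self, run_scenario):
        sc, rep = run_scenario("unique_panel")
        assert len(rep.cluster.members) == len(sc.targets)
        for pid, covered in rep.overlap.amplicon_to_targets.items():
            assert len(covered) == 1

    def test_each_target_covered_exactly_once(self, run_scenario):
        _, rep = run_scenario("overlap_cluster")
        seen = [t for ids in rep.overlap.amplicon_to_targets.values()
                for t in ids]
        assert len(seen) == len(set(seen))


class TestBruteForce:
    def test_single_target_no_checks(self):
        cands, targets = fixtures.random_cluster_instance(5, m=1, n=2,
                                                          uniform_k=2)
        cluster, stats = brute_force_cluster(cands, PARAMS, COND, targets)
        assert len(cluster.members) == 1
        assert stats.pairwise_checks == 0

    def test_complexity_formula_uniform_instance(self):
        # m=3 targets, n=2 candidates, k=2 nonspecific sites per primer:
        # C(3,2) * 4 * (n k) * (n k) = 3 * 4 * 16 = 192 pairwise checks
        cands, targets = fixtures.random_cluster_instance(9, m=3, n=2,
                                                          uniform_k=2)
        _, stats = brute_force_cluster(cands, PARAMS, COND, targets)
        assert stats.pairwise_checks == 192
        assert stats.k == 2.0

    def test_guard_refuses_large_instances(self):
        cands, targets = fixtures.random_cluster_instance(5, m=9, n=1)
        with pytest.raises(ValueError, match="too large"):
            brute_force_cluster(cands, PARAMS, COND, targets)
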