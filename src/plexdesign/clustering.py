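"""Multiplex compatibility and panel clustering.

Two primer pairs can share a PCR tube when they satisfy *unity* (product
lengths within 150 bp, pair-mean primer Tm within 5 C) and show no
*incompatibility*: no cross dimer over the dimer Tm threshold among the four
tagged primer combinations, and no more cross false amplicons (convergent
site pairs, one site from each pair, product containing no run target) than
the allowed budget.

The panel is assembled greedily: in each turn the remaining pair with the
fewest nonspecific binding sites becomes the next *seed*; incompatible pairs
of other targets (at budget 0) and the seeded target's other candidates are
deleted, until nothing remains.  Uncovered targets can then be re-admitted
by relaxing the cross-false-amplicon budget (0..4) without ever evicting a
member.  A brute-force optimal search over one-pair-per-target selections
serves as an oracle on small instances; its instrumented counter reproduces
the pairwise-check count C(m,2) * 4 * (n*k) * (n*k) on uniform-k instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from . import thermo
from .candidates import PrimerPair
from .genome_io import TargetRegion
from .oligo_align import cross_amplicons
from .params import DesignParameters, FailureRecord
from .thermo import ThermoConditions


@dataclass
class CompatibilityVerdict:
    compatible: bool
    violations: list[dict] = field(default_factory=list)
    cross_false_amplicon_count: int = 0


@dataclass
class MultiplexCluster:
    members: dict[str, PrimerPair] = field(default_factory=dict)
    seed_order: list[str] = field(default_factory=list)
    budget_used: dict[str, int] = field(default_factory=dict)
    uncovered: list[FailureRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class OverlapMap:
    """Assignment of every covered target to exactly one member amplicon."""

    amplicon_to_targets: dict[str, list[str]] = field(default_factory=dict)
    covering: dict[str, str] = field(default_factory=dict)


@dataclass
class ClusterInstanceStats:
    m: int
    n: int
    k: float
    pairwise_checks: int


def pair_unity(pa: PrimerPair, pb: PrimerPair, params: DesignParameters) -> bool:
    """Strict unity: |product length difference| < 150 bp and
    |pair-mean primer Tm difference| < 5 C (defaults)."""
    return (abs(pa.product_length - pb.product_length) < params.length_unity_bp
            and abs(pa.mean_tm - pb.mean_tm) < params.tm_unity_C)


@lru_cache(maxsize=200_000)
def _dimer_tm(seq1: str, seq2: str, conditions: ThermoConditions) -> float | None:
    res = thermo.heterodimer_eval(seq1, seq2, conditions)
    return res.tm_C if res.structure_found else None


def _sites(pair: PrimerPair):
    if pair.forward_sites is None or pair.reverse_sites is None:
        raise ValueError(f"{pair.pair_id}: binding sites not cached; run the "
                         "specificity filter first")
    return pair.forward_sites + pair.reverse_sites


def count_nonspecific_sites(pair: PrimerPair) -> int:
    """Total off-target (not intended) binding sites of both primers."""
    return sum(1 for s in _sites(pair) if not s.is_intended)


def cross_false_amplicon_count(pa: PrimerPair, pb: PrimerPair,
                               params: DesignParameters,
                               targets: list[TargetRegion]) -> int:
    amps = cross_amplicons(_sites(pa), _sites(pb), params, targets)
    return sum(1 for a in amps if not a.on_target)


def cross_pair_incompatibility(pa: PrimerPair, pb: PrimerPair,
                               params: DesignParameters,
                               conditions: ThermoConditions | None = None,
                               targets: list[TargetRegion] | None = None,
                               budget: int | None = None) -> CompatibilityVerdict:
    """Full pairwise test: unity, four cross-dimer combinations, cross false
    amplicons against the budget (defaults to the run's allowed budget)."""
    conditions = conditions or ThermoConditions()
    targets = targets or []
    if budget is None:
        budget = params.allowed_cross_false_alignments
    violations: list[dict] = []
    if abs(pa.product_length - pb.product_length) >= params.length_unity_bp:
        violations.append({"kind": "length_unity",
                           "magnitude": abs(pa.product_length - pb.product_length)})
    if abs(pa.mean_tm - pb.mean_tm) >= params.tm_unity_C:
        violations.append({"kind": "tm_unity",
                           "magnitude": abs(pa.mean_tm - pb.mean_tm)})
    combos = ((pa.effective_forward(), pb.effective_forward()),
              (pa.effective_forward(), pb.effective_reverse()),
              (pa.effective_reverse(), pb.effective_forward()),
              (pa.effective_reverse(), pb.effective_reverse()))
    for s1, s2 in combos:
        tm = _dimer_tm(s1, s2, conditions)
        if tm is not None and tm > params.dimer_tm_threshold:
            violations.append({"kind": "cross_dimer", "magnitude": tm})
    n_false = cross_false_amplicon_count(pa, pb, params, targets)
    if n_false > budget:
        violations.append({"kind": "cross_false_amplicon", "magnitude": n_false})
    return CompatibilityVerdict(not violations, violations, n_false)


def _seed_key(pair: PrimerPair):
    return (count_nonspecific_sites(pair), pair.penalty, pair.pair_id)


def greedy_seed_cluster(candidates_by_target: dict[str, list[PrimerPair]],
                        params: DesignParameters,
                        conditions: ThermoConditions | None = None,
                        targets: list[TargetRegion] | None = None) -> MultiplexCluster:
    """Seed-pair greedy clustering at budget 0.

    Each turn seeds the remaining pair with the fewest nonspecific binding
    sites (ties: lower penalty, then pair id); pairs of other targets that
    are incompatible with the seed are deleted, as are the seeded target's
    other candidates.  The result is pairwise compatible and maximal.
    """
    conditions = conditions or ThermoConditions()
    targets = targets or []
    pool: dict[str, list[PrimerPair]] = {t: list(ps) for t, ps in
                                         candidates_by_target.items() if ps}
    cluster = MultiplexCluster()
    blockers: dict[str, set[str]] = {t: set() for t in candidates_by_target}
    while pool:
        seed = min((p for ps in pool.values() for p in ps), key=_seed_key)
        cluster.members[seed.target_id] = seed
        cluster.seed_order.append(seed.pair_id)
        cluster.budget_used[seed.pair_id] = 0
        del pool[seed.target_id]
        for tid in list(pool):
            kept = []
            for p in pool[tid]:
                verdict = cross_pair_incompatibility(p, seed, params, conditions,
                                                     targets, budget=0)
                if verdict.compatible:
                    kept.append(p)
                else:
                    blockers[tid].add(seed.pair_id)
            if kept:
                pool[tid] = kept
            else:
                del pool[tid]
    for tid in sorted(candidates_by_target):
        if tid not in cluster.members and candidates_by_target[tid]:
            cluster.uncovered.append(FailureRecord(
                tid, "cluster",
                "all candidates incompatible with seeded cluster",
                {"blocking_seeds": sorted(blockers[tid])}))
    return cluster


def relax_cluster(cluster: MultiplexCluster,
                  leftover_candidates: dict[str, list[PrimerPair]],
                  budget: int,
                  params: DesignParameters,
                  conditions: ThermoConditions | None = None,
                  targets: list[TargetRegion] | None = None) -> MultiplexCluster:
    """Re-admit uncovered targets under a relaxed cross-false-amplicon budget.

    A candidate is addable when unity holds and no cross dimer exists against
    every current member, and its *total* cross false amplicons over all
    members is within the budget.  Addable candidates enter in order of
    fewest total cross false alignments; members are never evicted.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    conditions = conditions or ThermoConditions()
    targets = targets or []
    result = MultiplexCluster(dict(cluster.members), list(cluster.seed_order),
                              dict(cluster.budget_used), [])
    remaining = {tid: list(ps) for tid, ps in leftover_candidates.items()
                 if tid not in result.members and ps}
    while True:
        best = None
        for tid in sorted(remaining):
            for p in remaining[tid]:
                total = 0
                ok = True
                for member in result.members.values():
                    verdict = cross_pair_incompatibility(
                        p, member, params, conditions, targets, budget=budget)
                    if any(v["kind"] != "cross_false_amplicon"
                           for v in verdict.violations):
                        ok = False
                        break
                    total += verdict.cross_false_amplicon_count
                if ok and total <= budget:
                    key = (total, p.penalty, p.pair_id)
                    if best is None or key < best[0]:
                        best = (key, p, total)
        if best is None:
            break
        _, pair, total = best
        result.members[pair.target_id] = pair
        result.seed_order.append(pair.pair_id)
        result.budget_used[pair.pair_id] = total
        del remaining[pair.target_id]
    for rec in cluster.uncovered:
        if rec.target_id not in result.members:
            result.uncovered.append(rec)
    return result


def collapse_overlaps(cluster: MultiplexCluster,
                      all_targets: list[TargetRegion]) -> tuple[OverlapMap, MultiplexCluster]:
    """Remove member pairs whose target is wholly inside another member's
    on-target amplicon, assigning every covered target to one amplicon.

    Deterministic: amplicons covering the most targets keep their pairs
    first (ties by pair id)."""
    by_id = {t.target_id: t for t in all_targets}

    def covered_ids(pair: PrimerPair) -> list[str]:
        return [t.target_id for t in all_targets
                if t.chrom == pair.chrom
                and pair.product_start <= t.start and t.end <= pair.product_end]

    members = dict(cluster.members)
    order = sorted(members.values(),
                   key=lambda p: (-len(covered_ids(p)), p.pair_id))
    removed: dict[str, str] = {}
    kept: list[PrimerPair] = []
    for pair in order:
        if pair.target_id in removed:
            continue
        kept.append(pair)
        for other in order:
            if other.pair_id == pair.pair_id or other.target_id in removed:
                continue
            t = by_id[other.target_id]
            if (t.chrom == pair.chrom and pair.product_start <= t.start
                    and t.end <= pair.product_end):
                removed[other.target_id] = pair.pair_id
    omap = OverlapMap()
    for pair in kept:
        omap.amplicon_to_targets[pair.pair_id] = [pair.target_id]
        omap.covering[pair.target_id] = pair.pair_id
    for tid, cover in sorted(removed.items()):
        omap.amplicon_to_targets[cover].append(tid)
        omap.covering[tid] = cover
    # non-member targets swallowed by a kept amplicon (first cover in order)
    for pair in kept:
        for tid in covered_ids(pair):
            if tid not in omap.covering:
                omap.amplicon_to_targets[pair.pair_id].append(tid)
                omap.covering[tid] = pair.pair_id
    reduced = MultiplexCluster(
        {p.target_id: p for p in kept},
        [pid for pid in cluster.seed_order
         if pid in {p.pair_id for p in kept}],
        {p.pair_id: cluster.budget_used.get(p.pair_id, 0) for p in kept},
        list(cluster.uncovered))
    return omap, reduced


def brute_force_cluster(candidates_by_target: dict[str, list[PrimerPair]],
                        params: DesignParameters,
                        conditions: ThermoConditions | None = None,
                        targets: list[TargetRegion] | None = None,
                        max_targets: int = 8, max_candidates: int = 3,
                        ) -> tuple[MultiplexCluster, ClusterInstanceStats]:
    """Exhaustive optimal one-pair-per-target selection (budget 0).

    Guarded to m <= 8 targets and n <= 3 candidates per target.  The
    instrumented counter accumulates nonspecific-site x nonspecific-site
    comparisons over all four primer combinations of every cross-target
    candidate combination, the quantity the complexity expression
    C(m,2) * 4 * (n*k) * (n*k) counts.
    """
    conditions = conditions or ThermoConditions()
    targets = targets or []
    tids = sorted(candidates_by_target)
    m = len(tids)
    n = max((len(ps) for ps in candidates_by_target.values()), default=0)
    if m > max_targets or n > max_candidates:
        raise ValueError(f"instance too large for brute force: m={m} (max "
                         f"{max_targets}), n={n} (max {max_candidates})")
    checks = 0
    compat: dict[tuple[str, str], bool] = {}
    for i, j in itertools.combinations(range(m), 2):
        for pa in candidates_by_target[tids[i]]:
            for pb in candidates_by_target[tids[j]]:
                ka = [sum(1 for s in sites if not s.is_intended)
                      for sites in (pa.forward_sites or [], pa.reverse_sites or [])]
                kb = [sum(1 for s in sites if not s.is_intended)
                      for sites in (pb.forward_sites or [], pb.reverse_sites or [])]
                checks += sum(a * b for a in ka for b in kb)
                verdict = cross_pair_incompatibility(pa, pb, params, conditions,
                                                     targets, budget=0)
                compat[(pa.pair_id, pb.pair_id)] = verdict.compatible
                compat[(pb.pair_id, pa.pair_id)] = verdict.compatible

    best_sel: list[PrimerPair | None] = [None] * m
    best_count = -1
    chosen: list[PrimerPair | None] = [None] * m

    def dfs(idx: int, count: int):
        nonlocal best_count, best_sel
        if count + (m - idx) <= best_count:
            return
        if idx == m:
            if count > best_count:
                best_count = count
                best_sel = list(chosen)
            return
        for cand in candidates_by_target[tids[idx]]:
            if all(chosen[j] is None or compat[(cand.pair_id, chosen[j].pair_id)]
                   for j in range(idx)):
                chosen[idx] = cand
                dfs(idx + 1, count + 1)
                chosen[idx] = None
        dfs(idx + 1, count)

    dfs(0, 0)
    cluster = MultiplexCluster()
    for tid, pair in zip(tids, best_sel):
        if pair is not None:
            cluster.members[tid] = pair
            cluster.seed_order.append(pair.pair_id)
            cluster.budget_used[pair.pair_id] = 0
        elif candidates_by_target[tid]:
            cluster.uncovered.append(FailureRecord(
                tid, "cluster", "excluded by optimal selection"))
    nonspec = [sum(1 for s in ((p.forward_sites or []) if side == "f"
                               else (p.reverse_sites or []))
                   if not s.is_intended)
               for ps in candidates_by_target.values() for p in ps
               for side in ("f", "r")]
    k_mean = sum(nonspec) / len(nonspec) if nonspec else 0.0
    return cluster, ClusterInstanceStats(m, n, k_mean, checks)
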