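"""Deterministic synthetic genomes and design scenarios with known truth.

The generator builds small genomes in which every interesting behaviour of
the pipeline is *planted by construction*: each target sits in a "designable
island" locus — an AT-rich neighbourhood (in which essentially no substring
reaches the candidate Tm window) flanked by two engineered primer-quality
20-mers — so the top-ranked candidate pair is known exactly.  Decoy binding
motifs, cross-pair amplicon traps and mask entries are then planted using
those known primers, and a machine-checkable truth table records the
verdicts the pipeline must reproduce.

Scenario construction verifies its own invariants (the rank-1 candidate
equals the planted islands, planted decoys behave as intended) and retries
with fresh deterministic draws if a random background breaks them, so a
given (name, seed) always yields the same genome and truth table.

Planted decoy mutations are placed in the primer's 5' region: a 3'-intact
near-copy is both the off-target class that matters for PCR specificity and
the one whose detection by seed-and-extend alignment is guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

from . import thermo
from .candidates import enumerate_candidate_pairs
from .genome_io import (DesignWindow, GenomeReference, MaskTrack, TargetRegion,
                        extract_design_window, write_targets)
from .params import DesignParameters, FailureRecord
from .thermo import ThermoConditions

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_genome(seed: int, length: int, gc_fraction: float,
                    name: str = "chr1") -> GenomeReference:
    """I.i.d. random chromosome at the requested GC content."""
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = rng.choice(_BASES, size=length, p=p).tobytes().decode()
    return GenomeReference({name: seq})


@dataclass
class ScenarioSpec:
    """Recipe for one synthetic design scenario."""

    name: str
    seed: int
    genome_length: int
    #: background GC kept far below the candidate Tm window so the planted
    #: islands are the only primer-quality substrings of a locus
    gc_fraction: float = 0.12
    plants: list[dict] = field(default_factory=list)
    params: DesignParameters = field(default_factory=DesignParameters)
    tag_forward: str = ""
    tag_reverse: str = ""


@dataclass
class Scenario:
    """A materialised scenario: inputs plus the expected pipeline behaviour."""

    spec: ScenarioSpec
    genome: GenomeReference
    targets: list[TargetRegion]
    masks: MaskTrack
    truth: dict
    loci: dict = field(default_factory=dict)   # target_id -> planted locus info

    @property
    def params(self) -> DesignParameters:
        return self.spec.params

    @property
    def name(self) -> str:
        return self.spec.name

    def write(self, outdir) -> dict:
        """Emit genome FASTA and target/mask BEDs (CLI-ready inputs)."""
        import os
        os.makedirs(outdir, exist_ok=True)
        paths = {"genome": os.path.join(outdir, "genome.fasta"),
                 "targets": os.path.join(outdir, "targets.bed"),
                 "sites": os.path.join(outdir, "mask_sites.bed"),
                 "areas": os.path.join(outdir, "mask_areas.bed")}
        self.genome.to_fasta(paths["genome"])
        write_targets(self.targets, paths["targets"])
        for key, trees in (("sites", self.masks.sites), ("areas", self.masks.areas)):
            with open(paths[key], "w") as fh:
                for chrom in sorted(trees):
                    for iv in sorted(trees[chrom]):
                        fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\n")
        return paths


class PlantConflict(ValueError):
    """Two plants demanded overlapping genome real estate."""


class _Builder:
    """One construction attempt; raises _Retry if a random background
    violates a construction invariant."""

    class _Retry(Exception):
        pass

    def __init__(self, spec: ScenarioSpec, attempt: int):
        self.spec = spec
        self.rng = np.random.default_rng((spec.seed, attempt))
        self.params = spec.params
        self.conditions = ThermoConditions()
        genome = generate_genome(int(self.rng.integers(2**31)),
                                 spec.genome_length, spec.gc_fraction)
        self.chrom = next(iter(genome.chromosomes))
        self.seq = bytearray(genome.chromosomes[self.chrom], "ascii")
        self.targets: list[TargetRegion] = []
        self.site_tree = IntervalTree()
        self.area_tree = IntervalTree()
        self.truth: dict = {"pair_stage": {}, "target_stage": {}}
        self.loci: dict = {}
        self.occupied = IntervalTree()
        self.locus_cursor = 1200
        self.decoy_cursor: int | None = None
        self.accepted_oligos: list[str] = []

    # -- genome editing -------------------------------------------------
    def _write(self, pos: int, s: str, what: str) -> None:
        if pos < 0 or pos + len(s) > len(self.seq):
            raise PlantConflict(f"{what} at {pos} outside genome")
        if self.occupied.overlap(pos, pos + len(s)):
            hit = sorted(self.occupied.overlap(pos, pos + len(s)))[0]
            raise PlantConflict(f"{what} at {pos} collides with {hit.data}")
        self.occupied.addi(pos, pos + len(s), what)
        self.seq[pos:pos + len(s)] = s.encode()

    def _genome(self) -> GenomeReference:
        return GenomeReference({self.chrom: self.seq.decode()})

    # -- engineered primer oligos ---------------------------------------
    def _draw_oligo(self) -> str:
        length = self.params.primer_len_opt
        p = np.array([0.225, 0.275, 0.275, 0.225])
        for _ in range(4000):
            s = self.rng.choice(_BASES, size=length, p=p).tobytes().decode()
            gc = 100.0 * sum(b in "GC" for b in s) / length
            if not (45.0 <= gc <= 65.0):
                continue
            if abs(thermo.duplex_tm(s, self.conditions) - self.params.tm_opt) > 0.4:
                continue
            if self._structure_clean(s):
                self.accepted_oligos.append(s)
                return s
        raise RuntimeError("oligo rejection sampling exhausted")

    def _structure_clean(self, s: str) -> bool:
        tf, tr = self.spec.tag_forward, self.spec.tag_reverse
        variants = [tf + s, tr + s]
        for v in variants:
            hp = thermo.hairpin_eval(v, self.conditions)
            if hp.structure_found and hp.tm_C > 35.0:
                return False
        for prev in self.accepted_oligos:
            for a in (tf + s, tr + s):
                for b in (tf + prev, tr + prev):
                    d = thermo.heterodimer_eval(a, b, self.conditions)
                    if d.structure_found and d.tm_C > 35.0:
                        return False
        for a, b in ((tf + s, tr + s), (tf + s, tf + s)):
            d = thermo.heterodimer_eval(a, b, self.conditions)
            if d.structure_found and d.tm_C > 35.0:
                return False
        return True

    # -- plants ----------------------------------------------------------
    def plant_target(self, plant: dict) -> None:
        tid = plant["id"]
        tlen = plant.get("target_len", 2)
        product_len = plant.get("product_len",
                                int(self.rng.integers(250, 321)))
        f_seq = plant.get("forward_seq") or self._draw_oligo()
        r_seq = plant.get("reverse_seq") or self._draw_oligo()
        lp, lr = len(f_seq), len(r_seq)
        inner = product_len - lp - lr - tlen
        gap_f = inner // 2
        pos = plant.get("position", self.locus_cursor)
        f_start = pos
        t_start = pos + lp + gap_f
        r_start = pos + product_len - lr
        self._write(f_start, f_seq, f"target {tid} forward island")
        self._write(r_start, thermo.reverse_complement(r_seq),
                    f"target {tid} reverse island")
        self.targets.append(TargetRegion(self.chrom, t_start, t_start + tlen, tid))
        self.loci[tid] = {
            "forward_seq": f_seq, "reverse_seq": r_seq,
            "forward_start": f_start, "forward_end": f_start + lp,
            "reverse_start": r_start, "reverse_end": r_start + lr,
            "product": (f_start, f_start + product_len),
        }
        self.locus_cursor = max(self.locus_cursor, pos + product_len + 1400)

    def plant_tiled_targets(self, plant: dict) -> None:
        """One island pair whose product tiles several small targets."""
        ids = plant["ids"]
        product_len = plant.get("product_len", 300)
        tlen = plant.get("target_len", 2)
        f_seq = self._draw_oligo()
        r_seq = self._draw_oligo()
        lp, lr = len(f_seq), len(r_seq)
        pos = plant.get("position", self.locus_cursor)
        r_start = pos + product_len - lr
        self._write(pos, f_seq, f"tiled {ids[0]}.. forward island")
        self._write(r_start, thermo.reverse_complement(r_seq),
                    f"tiled {ids[0]}.. reverse island")
        inner_lo = pos + lp + 25
        inner_hi = r_start - 25 - tlen
        step = (inner_hi - inner_lo) // max(len(ids) - 1, 1)
        for i, tid in enumerate(ids):
            t_start = inner_lo + i * step
            self.targets.append(TargetRegion(self.chrom, t_start, t_start + tlen, tid))
            self.loci[tid] = {
                "forward_seq": f_seq, "reverse_seq": r_seq,
                "forward_start": pos, "forward_end": pos + lp,
                "reverse_start": r_start, "reverse_end": r_start + lr,
                "product": (pos, pos + product_len),
            }
        self.locus_cursor = max(self.locus_cursor, pos + product_len + 1400)

    def _alloc_decoy(self, extent: int) -> int:
        if self.decoy_cursor is None:
            self.decoy_cursor = self.locus_cursor + self.params.product_max + 600
        pos = self.decoy_cursor
        self.decoy_cursor += extent + 1600
        return pos

    def _mutate(self, s: str, n_mut: int) -> str:
        """Apply n substitutions in the 5' region (never the 3'-terminal 8)."""
        s = list(s)
        hi = max(len(s) - 8, 1)
        k = min(n_mut, hi)
        positions = self.rng.choice(np.arange(0, hi), size=k, replace=False)
        for p in positions:
            choices = [b for b in "ACGT" if b != s[p]]
            s[p] = choices[int(self.rng.integers(3))]
        return "".join(s)

    def plant_decoy_duplicate(self, plant: dict) -> None:
        tid = plant["of"]
        locus = self.loci[tid]
        n_mut = plant.get("mutations", 0)  # substitutions per primer motif
        f_copy = self._mutate(locus["forward_seq"], n_mut)
        r_copy = self._mutate(locus["reverse_seq"], n_mut)
        prod_len = locus["product"][1] - locus["product"][0]
        pos = plant.get("position", self._alloc_decoy(prod_len))
        self._write(pos, f_copy, f"decoy of {tid} (forward motif)")
        self._write(pos + prod_len - len(r_copy),
                    thermo.reverse_complement(r_copy),
                    f"decoy of {tid} (reverse motif)")
        f_detect = self._site_detectable(locus["forward_seq"], f_copy)
        r_detect = self._site_detectable(locus["reverse_seq"], r_copy)
        stage = "specificity" if (f_detect and r_detect) else "kept"
        self.truth["pair_stage"][f"{tid}-1"] = stage
        if stage != "kept":
            self.truth["target_stage"][tid] = "specificity"

    def _site_detectable(self, primer: str, site_seq: str) -> bool:
        """Evaluate the four binding conditions for a planted near-copy."""
        p = self.params
        mism = sum(a != b for a, b in zip(primer, site_seq))
        w = p.three_prime_mismatch_window
        tpm = sum(a != b for a, b in zip(primer[-w:], site_seq[-w:]))
        if (len(primer) < p.min_align_len or mism > p.max_mismatches
                or tpm > p.three_prime_mismatch_limit):
            return False
        dg = thermo.site_duplex_dG(primer, site_seq, self.conditions)
        return dg <= p.dg_threshold_kcal

    def plant_snp_site(self, plant: dict) -> None:
        tid = plant["target"]
        offset = plant["offset_from_3prime"]
        locus = self.loci[tid]
        # forward primer is on +: its 3' end is the island's right edge
        base = locus["forward_end"] - 1 - offset
        self.site_tree.addi(base, base + 1)
        inside = offset < self.params.three_prime_mask_window
        self.truth["pair_stage"][f"{tid}-1"] = "masked_site" if inside else "kept"
        if inside:
            self.truth["target_stage"][tid] = "masked_site"

    def plant_repeat_area(self, plant: dict) -> None:
        self.area_tree.addi(plant["start"], plant["end"])
        tid = plant.get("target")
        if tid:
            self.truth["pair_stage"][f"{tid}-1"] = "masked_area"
            self.truth["target_stage"][tid] = "masked_area"

    def plant_cross_trap(self, plant: dict) -> None:
        tid_a, tid_b = plant["a"], plant["b"]
        spacing = plant.get("spacing", 300)
        count = plant.get("count", 1)
        f_seq = self.loci[tid_a]["forward_seq"]
        r_seq = self.loci[tid_b]["reverse_seq"]
        for _ in range(count):
            extent = spacing
            pos = self._alloc_decoy(extent)
            self._write(pos, f_seq, f"cross trap {tid_a} forward motif")
            self._write(pos + spacing - len(r_seq),
                        thermo.reverse_complement(r_seq),
                        f"cross trap {tid_b} reverse motif")
        key = tuple(sorted((tid_a, tid_b)))
        cross = self.truth.setdefault("cross_counts", {})
        cross[key] = cross.get(key, 0) + count

    # -- reverse-engineering: record the designer's own rank-1 pair -------
    def design_rank1(self) -> None:
        """Run the candidate designer on the planted genome and overwrite each
        locus record with the actual rank-1 primers; decoys and traps are then
        planted from those, so truth tables are exact regardless of which
        island-neighbourhood variant ranks first."""
        genome = self._genome()
        for t in self.targets:
            window = extract_design_window(genome, t, self.params.product_max)
            result = enumerate_candidate_pairs(window, self.params, self.conditions)
            if isinstance(result, FailureRecord) or not result:
                raise _Builder._Retry(f"{t.target_id}: no candidates designed")
            top = result[0]
            locus = self.loci[t.target_id]
            # the designed pair must stay in the engineered island
            # neighbourhood, otherwise the AT filler failed its job
            if (abs(top.forward.genome_start - locus["forward_start"]) > 6
                    or abs(top.reverse.genome_end - locus["reverse_end"]) > 6):
                raise _Builder._Retry(f"{t.target_id}: rank-1 left the island")
            locus.update({
                "forward_seq": top.forward.sequence,
                "reverse_seq": top.reverse.sequence,
                "forward_start": top.forward.genome_start,
                "forward_end": top.forward.genome_end,
                "reverse_start": top.reverse.genome_start,
                "reverse_end": top.reverse.genome_end,
                "product": (top.product_start, top.product_end),
            })
        self._verify_designed_clean()

    def _verify_designed_clean(self) -> None:
        """The designed rank-1 pairs must pass the secondary-structure filters
        (individually and mutually): shifted island variants can pick up folds
        the oligo screen never saw."""
        tf, tr = self.spec.tag_forward, self.spec.tag_reverse
        tagged = []
        for tid, locus in self.loci.items():
            pair_tagged = (tf + locus["forward_seq"], tr + locus["reverse_seq"])
            for seq in pair_tagged:
                hp = thermo.hairpin_eval(seq, self.conditions)
                if hp.structure_found and hp.tm_C > self.params.hairpin_tm_threshold - 0.5:
                    raise _Builder._Retry(f"{tid}: designed primer folds ({hp.tm_C:.1f} C)")
            if pair_tagged not in tagged:
                tagged.append(pair_tagged)
        seqs = sorted({s for pair in tagged for s in pair})
        for i, a in enumerate(seqs):
            for b in seqs[i:]:
                d = thermo.heterodimer_eval(a, b, self.conditions)
                if d.structure_found and d.tm_C > self.params.dimer_tm_threshold - 0.5:
                    raise _Builder._Retry(f"designed primers dimerise ({d.tm_C:.1f} C)")

    def _verify_plants(self) -> None:
        """Planted specificity behaviour must hold exactly: pairs planted to
        fail specificity do, every other pair is clean, and cross false
        amplicon counts equal the planted trap counts.  Chance
        near-complementarities among the engineered motifs violate this
        occasionally; such attempts are retried with fresh draws."""
        from .candidates import PrimerPair
        from .clustering import cross_false_amplicon_count
        from .oligo_align import build_oligo_index
        from .pair_filters import specificity_filter
        genome = self._genome()
        index = build_oligo_index(genome, self.params.seed_k)
        designed: dict[str, PrimerPair] = {}
        for t in self.targets:
            locus = self.loci[t.target_id]
            from .candidates import PrimerCandidate
            fwd = PrimerCandidate("forward", locus["forward_seq"], self.chrom,
                                  locus["forward_start"], locus["forward_end"],
                                  "+", 60.0, 50.0)
            rev = PrimerCandidate("reverse", locus["reverse_seq"], self.chrom,
                                  locus["reverse_start"], locus["reverse_end"],
                                  "-", 60.0, 50.0)
            pair = PrimerPair(f"{t.target_id}-1", t.target_id, fwd, rev, 0.0)
            v = specificity_filter(pair, index, genome, self.params,
                                   self.conditions, self.targets)
            expected = self.truth["pair_stage"].get(f"{t.target_id}-1", "kept")
            if (expected == "specificity") is v.kept:
                raise _Builder._Retry(
                    f"{t.target_id}: specificity verdict {v.kept} vs planted "
                    f"{expected}")
            designed[t.target_id] = pair
        cross = self.truth.get("cross_counts", {})
        tids = sorted(designed)
        for i, a in enumerate(tids):
            for b in tids[i + 1:]:
                got = cross_false_amplicon_count(designed[a], designed[b],
                                                 self.params, self.targets)
                if got != cross.get((a, b), cross.get((b, a), 0)):
                    raise _Builder._Retry(
                        f"cross false amplicons {a}/{b}: {got} != planted")

    def build(self) -> Scenario:
        for plant in self.spec.plants:
            if plant["kind"] == "target":
                self.plant_target(plant)
            elif plant["kind"] == "tiled_targets":
                self.plant_tiled_targets(plant)
        self.design_rank1()
        for plant in self.spec.plants:
            kind = plant["kind"]
            if kind in ("target", "tiled_targets"):
                continue
            if kind == "decoy_duplicate":
                self.plant_decoy_duplicate(plant)
            elif kind == "snp_site":
                self.plant_snp_site(plant)
            elif kind == "repeat_area":
                self.plant_repeat_area(plant)
            elif kind == "cross_trap":
                self.plant_cross_trap(plant)
            else:
                raise ValueError(f"unknown plant kind {kind!r}")
        self._verify_plants()
        masks = MaskTrack()
        if self.site_tree:
            self.site_tree.merge_overlaps(strict=False)
            masks.sites[self.chrom] = self.site_tree
        if self.area_tree:
            self.area_tree.merge_overlaps(strict=False)
            masks.areas[self.chrom] = self.area_tree
        return Scenario(self.spec, self._genome(), list(self.targets),
                        masks, self.truth, self.loci)


def plant_scenario(spec: ScenarioSpec, max_attempts: int = 25) -> Scenario:
    """Materialise a scenario; deterministic in (spec.seed, spec contents)."""
    last = None
    for attempt in range(max_attempts):
        try:
            return _Builder(spec, attempt).build()
        except _Builder._Retry as exc:
            last = exc
    raise RuntimeError(f"scenario {spec.name!r} construction failed: {last}")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_PANEL_PARAMS = dict(product_min=200, product_max=340,
                     tm_min=58.0, tm_opt=60.0, tm_max=62.5)


def _params(n_candidates: int = 20, **extra) -> DesignParameters:
    return DesignParameters(**{**_PANEL_PARAMS,
                               "n_candidates_per_target": n_candidates, **extra})


def scenario_presets(seed: int = 11) -> dict[str, ScenarioSpec]:
    """The named scenarios used throughout the test surface.

    Every preset's truth table is exact by construction (see module doc).
    """
    presets: dict[str, ScenarioSpec] = {}

    n_clean = 20
    spec = ScenarioSpec("unique_panel", seed, 1200 + n_clean * 1800 + 2000,
                        plants=[{"kind": "target", "id": f"t{i:02d}"}
                                for i in range(1, n_clean + 1)],
                        params=_params(5))
    presets["unique_panel"] = spec

    presets["decoy_duplicate"] = ScenarioSpec(
        "decoy_duplicate", seed, 16000,
        plants=[{"kind": "target", "id": "t_dup"},
                {"kind": "target", "id": "t_weak"},
                {"kind": "decoy_duplicate", "of": "t_dup", "mutations": 0},
                {"kind": "decoy_duplicate", "of": "t_weak", "mutations": 10}],
        params=_params(1))

    presets["masked_3prime"] = ScenarioSpec(
        "masked_3prime", seed, 12000,
        plants=[{"kind": "target", "id": "t_mask"},
                {"kind": "target", "id": "t_ctrl"},
                {"kind": "snp_site", "target": "t_mask", "offset_from_3prime": 0},
                {"kind": "snp_site", "target": "t_ctrl", "offset_from_3prime": 7}],
        params=_params(1))

    presets["hairpin_trap"] = ScenarioSpec(
        "hairpin_trap", seed, 8000,
        plants=[{"kind": "target", "id": "t_hp"}],
        params=_params(1))

    presets["dimer_trap"] = ScenarioSpec(
        "dimer_trap", seed, 8000,
        plants=[{"kind": "target", "id": "t_dim"}],
        params=_params(1))

    presets["cross_pair_trap"] = ScenarioSpec(
        "cross_pair_trap", seed, 18000,
        plants=[{"kind": "target", "id": "t_a"},
                {"kind": "target", "id": "t_b"},
                {"kind": "cross_trap", "a": "t_a", "b": "t_b",
                 "spacing": 300, "count": 1}],
        params=_params(1))

    n_tiled = 5
    presets["overlap_cluster"] = ScenarioSpec(
        "overlap_cluster", seed, 8000,
        plants=[{"kind": "tiled_targets",
                 "ids": [f"ov{i}" for i in range(1, n_tiled + 1)],
                 "product_len": 300}],
        params=_params(1))

    clean, anchors, relaxed = 1, 4, 4
    plants = [{"kind": "target", "id": "t_clean1"}]
    plants += [{"kind": "target", "id": f"t_anchor{i}"} for i in range(1, anchors + 1)]
    plants += [{"kind": "target", "id": f"t_relax{i}"} for i in range(1, relaxed + 1)]
    plants += [{"kind": "cross_trap", "a": f"t_relax{i}", "b": f"t_anchor{i}",
                "spacing": 300, "count": i} for i in range(1, relaxed + 1)]
    presets["relaxation_ladder"] = ScenarioSpec(
        "relaxation_ladder", seed,
        1200 + (clean + anchors + relaxed) * 1800 + (1 + 2 + 3 + 4) * 2000 + 4000,
        plants=plants, params=_params(1))
    return presets


def random_cluster_instance(seed: int, m: int = 5, n: int = 2,
                            uniform_k: int | None = None,
                            params: DesignParameters | None = None):
    """Synthetic clustering instance: m targets x n candidate pairs with
    fabricated binding-site caches (no genome or alignment involved).

    Pairs get random primer sequences, product lengths and nonspecific sites;
    a fraction of the nonspecific sites land in shared hotspots on opposite
    strands, so cross false amplicons (and hence incompatibilities) occur.
    With ``uniform_k`` every primer gets exactly that many nonspecific sites,
    all on the + strand far apart (no accidental amplicons), which makes the
    brute-force pairwise-check count exactly C(m,2)*4*(n*k)^2.

    Returns (candidates_by_target, targets).
    """
    from .candidates import PrimerCandidate, PrimerPair
    from .oligo_align import BindingSite

    params = params or DesignParameters()
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    targets = []
    candidates: dict[str, list[PrimerPair]] = {}
    hotspots = [int(x) for x in rng.integers(60_000, 90_000, size=max(m, 3))]

    def rand_seq(length=20):
        return rng.choice(_BASES, size=length).tobytes().decode()

    def rand_sites(k: int, primer_len: int) -> list[BindingSite]:
        sites = []
        for _ in range(k):
            if uniform_k is not None:
                pos = int(rng.integers(100_000, 140_000))
                strand = "+"
            elif rng.random() < 0.45:
                hs = hotspots[int(rng.integers(len(hotspots)))]
                strand = "+" if rng.random() < 0.5 else "-"
                pos = hs + int(rng.integers(0, 200))
            else:
                pos = int(rng.integers(10_000, 50_000))
                strand = "+" if rng.random() < 0.5 else "-"
            sites.append(BindingSite(chrom, strand, pos, pos + primer_len,
                                     primer_len, 0, 0, -12.0, False))
        return sites

    for i in range(m):
        tid = f"s{i:02d}"
        t_start = 1000 + i * 2000
        targets.append(TargetRegion(chrom, t_start, t_start + 2, tid))
        pairs = []
        for j in range(n):
            plen = int(rng.integers(200, 340)) if uniform_k is None else 260
            f_seq, r_seq = rand_seq(), rand_seq()
            f_start = t_start - int(rng.integers(30, 90))
            r_end = f_start + plen
            tm_f = float(thermo.duplex_tm(f_seq)) if uniform_k is None else 58.0
            tm_r = float(thermo.duplex_tm(r_seq)) if uniform_k is None else 58.0
            fwd = PrimerCandidate("forward", f_seq, chrom, f_start, f_start + 20,
                                  "+", tm_f, 50.0)
            rev = PrimerCandidate("reverse", r_seq, chrom, r_end - 20, r_end,
                                  "-", tm_r, 50.0)
            pair = PrimerPair(f"{tid}-{j + 1}", tid, fwd, rev,
                              float(rng.random()),
                              tagged_forward=f_seq, tagged_reverse=r_seq)
            k_f = uniform_k if uniform_k is not None else int(rng.integers(0, 4))
            k_r = uniform_k if uniform_k is not None else int(rng.integers(0, 4))
            pair.forward_sites = ([BindingSite(chrom, "+", f_start, f_start + 20,
                                               20, 0, 0, -20.0, True)]
                                  + rand_sites(k_f, 20))
            pair.reverse_sites = ([BindingSite(chrom, "-", r_end - 20, r_end,
                                               20, 0, 0, -20.0, True)]
                                  + rand_sites(k_r, 20))
            pairs.append(pair)
        candidates[tid] = pairs
    return candidates, targets


def build_scenario(name: str, seed: int = 11) -> Scenario:
    """Materialise one named preset (see :func:`scenario_presets`)."""
    presets = scenario_presets(seed)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    spec = presets[name]
    scenario = plant_scenario(spec)
    return _finalise_preset(name, scenario)


def _finalise_preset(name: str, scenario: Scenario) -> Scenario:
    """Attach preset-specific truth and scenario surgery."""
    truth = scenario.truth
    tids = [t.target_id for t in scenario.targets]

    if name == "unique_panel":
        truth["clustered"] = sorted(tids)
        truth["uncovered"] = []
        truth["final_pairs"] = len(tids)

    elif name == "decoy_duplicate":
        truth["clustered"] = ["t_weak"]
        truth["uncovered"] = []

    elif name == "masked_3prime":
        truth["clustered"] = ["t_ctrl"]
        truth["uncovered"] = []

    elif name == "hairpin_trap":
        # fold the tagged forward primer back on itself: the tag carries the
        # reverse complement of the primer's first 12 bases ahead of a
        # non-pairing spacer, giving a 12 bp stem / 4 nt loop
        f_seq = scenario.loci["t_hp"]["forward_seq"]
        tag = thermo.reverse_complement(f_seq[:12]) + "AAAA"
        scenario = replace(scenario, spec=replace(scenario.spec, tag_forward=tag))
        hp = thermo.hairpin_eval(tag + f_seq)
        assert hp.structure_found and hp.tm_C > scenario.params.hairpin_tm_threshold
        truth["pair_stage"]["t_hp-1"] = "hairpin"
        truth["target_stage"]["t_hp"] = "hairpin"
        truth["clustered"] = []
        truth["uncovered"] = []

    elif name == "dimer_trap":
        # rewrite the reverse island so the reverse primer is the exact
        # reverse complement of the forward primer
        locus = scenario.loci["t_dim"]
        f_seq = locus["forward_seq"]
        chrom = next(iter(scenario.genome.chromosomes))
        seq = bytearray(scenario.genome.chromosomes[chrom], "ascii")
        r0 = locus["reverse_start"]
        seq[r0:r0 + len(f_seq)] = f_seq.encode()   # length-preserving overwrite
        locus["reverse_seq"] = thermo.reverse_complement(f_seq)
        scenario = replace(scenario,
                           genome=GenomeReference({chrom: seq.decode()}))
        d = thermo.heterodimer_eval(f_seq, thermo.reverse_complement(f_seq))
        assert d.structure_found and d.tm_C > scenario.params.dimer_tm_threshold
        truth["pair_stage"]["t_dim-1"] = "dimer"
        truth["target_stage"]["t_dim"] = "dimer"
        truth["clustered"] = []
        truth["uncovered"] = []

    elif name == "cross_pair_trap":
        truth["covered_by_budget"] = {0: 1, 1: 2, 2: 2, 3: 2, 4: 2}

    elif name == "overlap_cluster":
        truth["clustered"] = sorted(tids)
        truth["final_pairs"] = 1
        truth["covered_per_amplicon"] = len(tids)

    elif name == "relaxation_ladder":
        base = 1 + 4  # clean + anchor-or-relax winners of each trap pair
        truth["covered_by_budget"] = {b: base + sum(1 for i in range(1, 5) if i <= b)
                                      for b in range(5)}
    return scenario
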