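"""Genome-wide primer binding-site discovery and amplicon prediction.

A k-mer index over the reference provides seed hits; every k-mer of the
primer is used as a seed and each hit is extended ungapped over the full
primer length.  A genome location is a binding site when the four annealing
conditions all hold:

  1. the aligned span is at least ``min_align_len`` (the full primer must fit
     inside the chromosome; partial/gapped alignments are not modelled),
  2. at most ``max_mismatches`` mismatches overall,
  3. at most ``three_prime_mismatch_limit`` mismatches within the 3'-terminal
     ``three_prime_mismatch_window`` bases,
  4. annealing dG at or below ``dg_threshold_kcal`` (strong binding).

Candidate alignment offsets come from one of two modes.  For references up
to a few megabases (every desk-scale design, the default "auto" choice) a
vectorised every-offset mismatch prefilter makes discovery *exhaustive*: the
reported site set is exactly the set passing the four conditions.  For
larger references the k-mer seeded mode is used: seeds identify candidate
regions and every register of both strands within a primer length of a seed
hit is scored (which also captures near-palindromic opposite-strand sites
co-located with a seeded region).  Seeded discovery is guaranteed to find
any site lying within a primer length of an exact k-mer match of the primer;
sites with so many scattered mismatches that no k-mer in their whole
neighbourhood survives cannot be seeded — with the mismatch counts that
also pass the dG condition these are vanishingly rare, which is why the
seeded mode is a sound approximation at genome scale.

Two binding sites form a predicted amplicon when they are on one chromosome,
convergent (3' ends facing), and their outermost-5'-to-outermost-5' span is
within ``max_amplicon_span``.  All three primer pairings are considered:
forward-reverse, forward-forward and reverse-reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import thermo
from .candidates import PrimerCandidate
from .genome_io import GenomeReference, TargetRegion
from .params import DesignParameters
from .thermo import ThermoConditions


@dataclass
class OligoIndex:
    """Exact k-mer postings over the + strand of every chromosome.

    Reverse-strand occurrences are resolved at query time by looking up the
    reverse complement, so storage is single-stranded.
    """

    k: int
    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.postings.get(kmer, [])


def build_oligo_index(genome: GenomeReference, k: int = 12) -> OligoIndex:
    """Index every ACGT k-mer occurrence; k-mers touching N are skipped."""
    if not (8 <= k <= 16):
        raise ValueError("k must be in [8, 16]")
    postings: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.chromosomes.items():
        n = len(seq)
        # positions covered by N poison any k-mer overlapping them
        next_n = [n] * (n + 1)
        for i in range(n - 1, -1, -1):
            next_n[i] = i if seq[i] == "N" else next_n[i + 1]
        for i in range(n - k + 1):
            if next_n[i] < i + k:
                continue
            postings.setdefault(seq[i:i + k], []).append((chrom, i))
    return OligoIndex(k=k, postings=postings)


@dataclass(frozen=True)
class BindingSite:
    """One genome location where a primer can anneal (all four conditions met)."""

    chrom: str
    strand: str                      # strand whose sense matches the primer
    site_start: int
    site_end: int
    aligned_len: int
    mismatches: int
    three_prime_terminal_mismatches: int
    dg_kcal_mol: float
    is_intended: bool

    @property
    def five_prime(self) -> int:
        """Outermost 5' genome coordinate of the annealed primer."""
        return self.site_start if self.strand == "+" else self.site_end

    @property
    def three_prime_facing_right(self) -> bool:
        return self.strand == "+"


@dataclass(frozen=True)
class PredictedAmplicon:
    site_a: BindingSite              # the + strand (leftward) site
    site_b: BindingSite              # the - strand (rightward) site
    orientation: str                 # "FR" | "FF" | "RR"
    span: int
    on_target: bool
    covered_target_ids: tuple[str, ...]

    @property
    def chrom(self) -> str:
        return self.site_a.chrom

    @property
    def start(self) -> int:
        return self.site_a.site_start

    @property
    def end(self) -> int:
        return self.site_b.site_end


#: total reference size (bp) up to which "auto" mode scans exhaustively
EXHAUSTIVE_LIMIT_BP = 2_000_000
_CHUNK = 1 << 18


def _seeded_offsets(seq: str, rc: str, index: OligoIndex,
                    lengths: dict[str, int]) -> set[tuple[str, str, int]]:
    L, k = len(seq), index.k
    anchors: set[tuple[str, int]] = set()
    for q in range(L - k + 1):
        for chrom, pos in index.lookup(seq[q:q + k]):
            anchors.add((chrom, pos - q))
        for chrom, pos in index.lookup(rc[q:q + k]):
            anchors.add((chrom, pos - q))
    offsets: set[tuple[str, str, int]] = set()
    for chrom, anchor in anchors:
        for off in range(anchor - L, anchor + L + 1):
            if 0 <= off and off + L <= lengths[chrom]:
                offsets.add((chrom, "+", off))
                offsets.add((chrom, "-", off))
    return offsets


def _exhaustive_offsets(seq: str, rc: str, genome: GenomeReference,
                        max_mismatches: int) -> set[tuple[str, str, int]]:
    """Every-offset mismatch prefilter (vectorised, chunked)."""
    L = len(seq)
    p_plus = np.frombuffer(seq.encode(), dtype=np.uint8)
    p_minus = np.frombuffer(rc.encode(), dtype=np.uint8)
    offsets: set[tuple[str, str, int]] = set()
    for chrom, s in genome.chromosomes.items():
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        if len(arr) < L:
            continue
        for lo in range(0, len(arr) - L + 1, _CHUNK):
            hi = min(lo + _CHUNK + L - 1, len(arr))
            win = np.lib.stride_tricks.sliding_window_view(arr[lo:hi], L)
            for strand, pat in (("+", p_plus), ("-", p_minus)):
                mism = (win != pat).sum(axis=1)
                for off in np.nonzero(mism <= max_mismatches)[0]:
                    offsets.add((chrom, strand, lo + int(off)))
    return offsets


def find_binding_sites(primer: PrimerCandidate, index: OligoIndex,
                       genome: GenomeReference, params: DesignParameters,
                       conditions: ThermoConditions | None = None,
                       table=None, mode: str = "auto") -> list[BindingSite]:
    """All genome-wide binding sites of one primer, sorted by position.

    ``mode`` is "auto" (exhaustive up to ``EXHAUSTIVE_LIMIT_BP`` of total
    reference, seeded beyond), "exhaustive" or "seeded".  The primer's own
    design location is flagged ``is_intended``.
    """
    conditions = conditions or ThermoConditions()
    table = table or thermo.default_table()
    seq = primer.sequence
    L = len(seq)
    if L < index.k:
        raise ValueError(f"primer ({L} nt) shorter than seed length {index.k}")
    if L < params.min_align_len:
        return []
    rc = thermo.reverse_complement(seq)
    lengths = genome.lengths

    if mode not in ("auto", "seeded", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = ("exhaustive" if sum(lengths.values()) <= EXHAUSTIVE_LIMIT_BP
                else "seeded")
    if mode == "exhaustive":
        offsets = _exhaustive_offsets(seq, rc, genome, params.max_mismatches)
    else:
        offsets = _seeded_offsets(seq, rc, index, lengths)

    w = params.three_prime_mismatch_window
    sites: list[BindingSite] = []
    for chrom, strand, off in sorted(offsets):
        slice_ = genome.fetch(chrom, off, off + L)
        site_sense = slice_ if strand == "+" else thermo.reverse_complement(slice_)
        mism = [a != b or b == "N" for a, b in zip(seq, site_sense)]
        n_mism = sum(mism)
        if n_mism > params.max_mismatches:
            continue
        tpm = sum(mism[-w:]) if w else 0
        if tpm > params.three_prime_mismatch_limit:
            continue
        dg = thermo.site_duplex_dG(seq, site_sense, conditions, table)
        if dg > params.dg_threshold_kcal:
            continue
        intended = (chrom == primer.chrom and strand == primer.strand
                    and off == primer.genome_start)
        sites.append(BindingSite(chrom, strand, off, off + L, L, n_mism, tpm,
                                 dg, intended))
    return sites


def _convergent_amplicons(plus_sites, minus_sites, max_span):
    for a in plus_sites:
        for b in minus_sites:
            if a.chrom != b.chrom:
                continue
            if a.site_start > b.site_start:
                continue
            span = b.site_end - a.site_start
            if 0 < span <= max_span:
                yield a, b, span


def predict_amplicons(sites_f: list[BindingSite], sites_r: list[BindingSite],
                      params: DesignParameters,
                      targets: list[TargetRegion],
                      own_target_ids: set[str] | None = None) -> list[PredictedAmplicon]:
    """Predicted products from the binding sites of one primer pair.

    Orientations: FR (one site from each primer), FF and RR (two sites of the
    same primer on opposite strands).  ``on_target`` requires both sites to be
    the intended ones and the product interval to contain at least one of the
    pair's own targets; ``covered_target_ids`` lists every run target wholly
    inside the product.
    """
    own = own_target_ids or set()
    out: list[PredictedAmplicon] = []

    def covered(chrom, start, end):
        return tuple(t.target_id for t in targets
                     if t.chrom == chrom and start <= t.start and t.end <= end)

    def emit(a, b, span, orientation):
        ids = covered(a.chrom, a.site_start, b.site_end)
        on = (a.is_intended and b.is_intended
              and any(t in own for t in ids))
        out.append(PredictedAmplicon(a, b, orientation, span, on, ids))

    f_plus = [s for s in sites_f if s.strand == "+"]
    f_minus = [s for s in sites_f if s.strand == "-"]
    r_plus = [s for s in sites_r if s.strand == "+"]
    r_minus = [s for s in sites_r if s.strand == "-"]

    for a, b, span in _convergent_amplicons(f_plus, r_minus, params.max_amplicon_span):
        emit(a, b, span, "FR")
    for a, b, span in _convergent_amplicons(r_plus, f_minus, params.max_amplicon_span):
        emit(a, b, span, "FR")
    for a, b, span in _convergent_amplicons(f_plus, f_minus, params.max_amplicon_span):
        emit(a, b, span, "FF")
    for a, b, span in _convergent_amplicons(r_plus, r_minus, params.max_amplicon_span):
        emit(a, b, span, "RR")
    return out


def cross_amplicons(sites_1: list[BindingSite], sites_2: list[BindingSite],
                    params: DesignParameters,
                    targets: list[TargetRegion]) -> list[PredictedAmplicon]:
    """Convergent products with one site from each of two different primers.

    Products whose interval contains no run target are the cross false
    amplicons counted against the multiplex compatibility budget.
    """
    out: list[PredictedAmplicon] = []

    def covered(chrom, start, end):
        return tuple(t.target_id for t in targets
                     if t.chrom == chrom and start <= t.start and t.end <= end)

    plus_1 = [s for s in sites_1 if s.strand == "+"]
    minus_1 = [s for s in sites_1 if s.strand == "-"]
    plus_2 = [s for s in sites_2 if s.strand == "+"]
    minus_2 = [s for s in sites_2 if s.strand == "-"]
    for p, m in ((plus_1, minus_2), (plus_2, minus_1)):
        for a, b, span in _convergent_amplicons(p, m, params.max_amplicon_span):
            ids = covered(a.chrom, a.site_start, b.site_end)
            out.append(PredictedAmplicon(a, b, "FR", span, bool(ids), ids))
    return out
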