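"""Candidate primer-pair generation within a design window.

All primers satisfying the length/Tm/GC bounds are enumerated exhaustively on
both flanks of the target (the forward primer entirely 5' of the target, the
reverse entirely 3', so the amplicon always contains the whole target
interval), then paired by product size and ranked by a penalty

    w_tm * (|Tm_F - Tm_opt| + |Tm_R - Tm_opt|)
      + w_len * (|len_F - len_opt| + |len_R - len_opt|)

with deterministic tie-breaking (smaller product, leftmost forward start,
lexicographic sequences).  Tm evaluation over all substrings uses prefix sums
of the nearest-neighbour stack contributions, so enumeration is linear in
window length per primer length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import thermo
from .genome_io import DesignWindow
from .params import DesignParameters, FailureRecord
from .thermo import R_GAS, ThermoConditions

#: hard cap per side fed into pairwise ranking; pairing falls back to the
#: full candidate sets when the pruned sets admit no size-compatible pair.
_MAX_SIDE = 400


@dataclass(frozen=True)
class PrimerCandidate:
    """One oriented oligo.  ``sequence`` is 5'->3'; for a reverse primer it is
    the reverse complement of the genome slice [genome_start, genome_end)."""

    side: str                     # "forward" | "reverse"
    sequence: str
    chrom: str
    genome_start: int
    genome_end: int
    strand: str                   # "+" | "-"
    tm_C: float
    gc_percent: float

    def __post_init__(self):
        if self.side not in ("forward", "reverse"):
            raise ValueError(f"bad side {self.side!r}")
        expected = "+" if self.side == "forward" else "-"
        if self.strand != expected:
            raise ValueError(f"{self.side} primer must be on {expected} strand")
        if len(self.sequence) != self.genome_end - self.genome_start:
            raise ValueError("sequence length does not match coordinates")
        if not (0 <= self.gc_percent <= 100):
            raise ValueError("gc_percent out of range")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def three_prime_interval(self, window: int) -> tuple[int, int]:
        """Genome interval of the 3'-terminal ``window`` bases (strand-aware)."""
        w = min(window, self.length)
        if self.strand == "+":
            return self.genome_end - w, self.genome_end
        return self.genome_start, self.genome_start + w


@dataclass
class PrimerPair:
    pair_id: str
    target_id: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    penalty: float
    tagged_forward: str | None = None
    tagged_reverse: str | None = None
    # caches populated by the specificity filter, consumed by clustering
    forward_sites: list | None = None
    reverse_sites: list | None = None

    def __post_init__(self):
        if self.forward.chrom != self.reverse.chrom:
            raise ValueError("pair spans chromosomes")
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.product_length <= 0:
            raise ValueError("non-positive product length")

    @property
    def chrom(self) -> str:
        return self.forward.chrom

    @property
    def product_start(self) -> int:
        return self.forward.genome_start

    @property
    def product_end(self) -> int:
        return self.reverse.genome_end

    @property
    def product_length(self) -> int:
        return self.product_end - self.product_start

    @property
    def mean_tm(self) -> float:
        return 0.5 * (self.forward.tm_C + self.reverse.tm_C)

    def effective_forward(self) -> str:
        return self.tagged_forward if self.tagged_forward is not None else self.forward.sequence

    def effective_reverse(self) -> str:
        return self.tagged_reverse if self.tagged_reverse is not None else self.reverse.sequence


def _stack_prefix(seq: str, table: thermo.NNParameterTable):
    """Cumulative dH/dS of the NN stacks of ``seq`` against its complement.

    Positions containing N (or any non-ACGT) poison every substring that
    covers them, tracked via a prefix count.
    """
    n = len(seq)
    dh = np.zeros(n, dtype=float)
    ds = np.zeros(n, dtype=float)
    bad = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        bad[i + 1] = bad[i] + (seq[i] not in "ACGT")
    for i in range(n - 1):
        a, b = seq[i], seq[i + 1]
        if a in "ACGT" and b in "ACGT":
            h, s = table.stack(a + b, thermo.complement(a) + thermo.complement(b))
            dh[i], ds[i] = h, s
    gc = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        gc[i + 1] = gc[i] + (seq[i] in "GC")
    return np.concatenate([[0.0], np.cumsum(dh)]), np.concatenate([[0.0], np.cumsum(ds)]), gc, bad


def _substring_tm(seq, dh_cum, ds_cum, starts, length, table, conditions):
    """Vectorised duplex Tm for all substrings seq[i:i+length], i in starts."""
    init_h, init_s = table.init("init")
    at_h, at_s = table.init("init_A/T")
    is_at = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_at = (is_at == ord("A")) | (is_at == ord("T"))
    ends = starts + length
    n_at = is_at[starts].astype(float) + is_at[ends - 1].astype(float)
    dh = dh_cum[ends - 1] - dh_cum[starts] + init_h + at_h * n_at
    ds = ds_cum[ends - 1] - ds_cum[starts] + init_s + at_s * n_at
    na_eq = conditions.monovalent_equivalent_M()
    ds = ds + 0.368 * (length - 1) * math.log(na_eq)
    k = conditions.oligo_nM * 1e-9 / 4.0
    tm = dh * 1000.0 / (ds + R_GAS * math.log(k)) - 273.15
    return tm - 0.6 * conditions.dmso_percent


def _enumerate_side(window: DesignWindow, params: DesignParameters,
                    conditions: ThermoConditions, table, side: str) -> list[PrimerCandidate]:
    seq = window.sequence
    n = len(seq)
    target = window.target
    dh_cum, ds_cum, gc_cum, bad_cum = _stack_prefix(seq, table)
    out: list[PrimerCandidate] = []
    for length in range(params.primer_len_min, params.primer_len_max + 1):
        if length > n:
            continue
        if side == "forward":
            # 3' end at or before the target start
            hi = target.start - window.offset - length
            starts = np.arange(0, hi + 1) if hi >= 0 else np.empty(0, dtype=int)
        else:
            lo = target.end - window.offset
            starts = np.arange(max(lo, 0), n - length + 1)
        if starts.size == 0:
            continue
        ends = starts + length
        ok = (bad_cum[ends] - bad_cum[starts]) == 0
        gc = (gc_cum[ends] - gc_cum[starts]) * 100.0 / length
        ok &= (gc >= params.gc_min) & (gc <= params.gc_max)
        if not ok.any():
            continue
        tm = np.full(starts.shape, np.nan)
        tm[ok] = _substring_tm(seq, dh_cum, ds_cum, starts[ok], length, table, conditions)
        # loose pre-filter via prefix sums, then the exact scalar evaluation
        # (which also covers the self-complementary correction)
        ok &= (tm >= params.tm_min - 0.5) & (tm <= params.tm_max + 0.5)
        for i, e, g in zip(starts[ok], ends[ok], gc[ok]):
            gs, ge = window.offset + int(i), window.offset + int(e)
            sub = seq[i:e]
            t = thermo.duplex_tm(sub, conditions, table)
            if not (params.tm_min <= t <= params.tm_max):
                continue
            if side == "forward":
                out.append(PrimerCandidate("forward", sub, target.chrom, gs, ge, "+",
                                           float(t), float(g)))
            else:
                out.append(PrimerCandidate("reverse", thermo.reverse_complement(sub),
                                           target.chrom, gs, ge, "-", float(t), float(g)))
    return out


def _candidate_penalty(c: PrimerCandidate, params: DesignParameters) -> float:
    return (params.w_tm * abs(c.tm_C - params.tm_opt)
            + params.w_len * abs(c.length - params.primer_len_opt))


def _rank_pairs(forwards, reverses, params) -> list[tuple]:
    keyed = []
    for f in forwards:
        pf = _candidate_penalty(f, params)
        for r in reverses:
            plen = r.genome_end - f.genome_start
            if not (params.product_min <= plen <= params.product_max):
                continue
            pen = pf + _candidate_penalty(r, params)
            keyed.append((pen, plen, f.genome_start, f.sequence + r.sequence, f, r))
    keyed.sort(key=lambda t: t[:4])
    return keyed


def enumerate_candidate_pairs(window: DesignWindow, params: DesignParameters,
                              conditions: ThermoConditions | None = None,
                              table=None) -> list[PrimerPair] | FailureRecord:
    """Design up to ``n_candidates_per_target`` ranked primer pairs, or
    explain why none exist with a stage="design" failure record."""
    conditions = conditions or ThermoConditions()
    table = table or thermo.default_table()
    tid = window.target.target_id
    if len(window.sequence) < params.primer_len_min:
        return FailureRecord(tid, "design", "window too small",
                             {"window_length": len(window.sequence)})
    forwards = _enumerate_side(window, params, conditions, table, "forward")
    reverses = _enumerate_side(window, params, conditions, table, "reverse")
    if not forwards or not reverses:
        return FailureRecord(tid, "design", "no candidate primers",
                             {"left_primers": len(forwards),
                              "right_primers": len(reverses)})

    def prune(cands):
        return sorted(cands, key=lambda c: (_candidate_penalty(c, params),
                                            c.genome_start, c.sequence))[:_MAX_SIDE]

    ranked = _rank_pairs(prune(forwards), prune(reverses), params)
    if not ranked and (len(forwards) > _MAX_SIDE or len(reverses) > _MAX_SIDE):
        ranked = _rank_pairs(forwards, reverses, params)
    if not ranked:
        return FailureRecord(tid, "design", "product size",
                             {"left_primers": len(forwards),
                              "right_primers": len(reverses)})
    pairs = []
    for rank, (pen, _plen, _fs, _seqs, f, r) in enumerate(
            ranked[:params.n_candidates_per_target], start=1):
        pairs.append(PrimerPair(f"{tid}-{rank}", tid, f, r, pen))
    return pairs


def attach_tags(pair: PrimerPair, tag_forward: str, tag_reverse: str) -> PrimerPair:
    """Prepend constant 5' tags; untagged fields are untouched."""
    for tag in (tag_forward, tag_reverse):
        if any(b not in "ACGT" for b in tag):
            raise ValueError(f"tag must be an ACGT string: {tag!r}")
    return replace(pair,
                   tagged_forward=tag_forward + pair.forward.sequence,
                   tagged_reverse=tag_reverse + pair.reverse.sequence)
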