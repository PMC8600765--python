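"""Independent reference implementations used to cross-check the package.

These deliberately take different code paths from the implementation:
melting temperatures come from Biopython's nearest-neighbour routine, free
energies from a direct re-summation over Biopython's parameter dictionaries,
binding sites from a vectorised every-offset scan, and hairpins from a
stem-triple enumeration.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt

from plexdesign import thermo
from plexdesign.oligo_align import BindingSite

R = 1.987


def tm_oracle(seq: str, conditions) -> float:
    """Duplex Tm via Biopython's independent NN summation."""
    return mt.Tm_NN(seq, nn_table=mt.DNA_NN4,
                    Na=conditions.monovalent_mM, K=0, Tris=0,
                    Mg=conditions.divalent_mM, dNTPs=conditions.dNTP_mM,
                    dnac1=conditions.oligo_nM / 2, dnac2=conditions.oligo_nM / 2,
                    saltcorr=5)


def dg_oracle(primer: str, site: str, conditions) -> float:
    """Annealing dG by direct summation over Biopython's parameter tables.

    Same model conventions as the implementation (isolated internal
    mismatches from the mismatch table, mismatch runs and terminal
    mismatches unstacked, SantaLucia-1998 entropy salt correction) but
    written as an independent walk over independent dictionaries.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    n = len(primer)
    mism = [primer[i] != site[i] or site[i] == "N" for i in range(n)]
    dh, ds = mt.DNA_NN4["init"]
    for idx in (0, n - 1):
        if not mism[idx]:
            h, s = mt.DNA_NN4["init_A/T" if primer[idx] in "AT" else "init_G/C"]
            dh += h
            ds += s

    def lookup(table, key):
        if key in table:
            return table[key]
        top, bottom = key.split("/")
        return table.get(bottom[::-1] + "/" + top[::-1])

    for i in range(n - 1):
        a, b = mism[i], mism[i + 1]
        key = (primer[i] + primer[i + 1] + "/"
               + comp[site[i]] + comp[site[i + 1]])
        if not a and not b:
            h, s = lookup(mt.DNA_NN4, key)
        elif a != b:
            pos = i if a else i + 1
            isolated = (0 < pos < n - 1 and not mism[pos - 1] and not mism[pos + 1])
            entry = lookup(mt.DNA_IMM1, key) if isolated else None
            h, s = entry if entry is not None else (0.0, 0.0)
        else:
            h, s = 0.0, 0.0
        dh += h
        ds += s
    na_eq = conditions.monovalent_equivalent_M()
    ds += 0.368 * (n - 1) * math.log(na_eq)
    return dh - (conditions.dg_temperature_C + 273.15) * ds / 1000.0


def scan_binding_sites(primer_seq: str, genome, params, conditions,
                       intended=None) -> list[BindingSite]:
    """Exhaustive every-offset, both-strand scan applying the four binding
    conditions; the reference for seed-and-extend site discovery."""
    sites = []
    L = len(primer_seq)
    if L < params.min_align_len:
        return sites
    w = params.three_prime_mismatch_window
    primer_arr = np.frombuffer(primer_seq.encode(), dtype=np.uint8)
    for chrom, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand in "+-":
            if strand == "+":
                sense = windows
                cmp = primer_arr
            else:
                # site sense = revcomp(slice); compare primer revcomp to slice
                cmp = np.frombuffer(
                    thermo.reverse_complement(primer_seq).encode(), dtype=np.uint8)
                sense = windows
            mism_total = (sense != cmp).sum(axis=1) + (sense == ord("N")).sum(
                axis=1) - ((sense != cmp) & (sense == ord("N"))).sum(axis=1)
            for off in np.nonzero(mism_total <= params.max_mismatches)[0]:
                slice_ = seq[off:off + L]
                site_sense = (slice_ if strand == "+"
                              else thermo.reverse_complement(slice_))
                flags = [a != b or b == "N"
                         for a, b in zip(primer_seq, site_sense)]
                n_mism = sum(flags)
                if n_mism > params.max_mismatches:
                    continue
                if sum(flags[-w:]) > params.three_prime_mismatch_limit:
                    continue
                dg = thermo.site_duplex_dG(primer_seq, site_sense, conditions)
                if dg > params.dg_threshold_kcal:
                    continue
                is_int = bool(intended and intended == (chrom, strand, int(off)))
                sites.append(BindingSite(chrom, strand, int(off), int(off) + L,
                                         L, n_mism, sum(flags[-w:]), dg, is_int))
    sites.sort(key=lambda s: (s.chrom, s.strand, s.site_start))
    return sites


def hairpin_best_tm(seq: str, conditions) -> float | None:
    """Best hairpin Tm by brute-force enumeration of (start, end, stem) triples."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = len(seq)
    best = None
    for i in range(n):
        for j in range(n):
            for stem in range(3, n):
                if j - stem + 1 <= i + stem - 1 + 3:
                    break
                top = seq[i:i + stem]
                bottom = seq[j - stem + 1:j + 1]
                if any(comp[top[t]] != bottom[stem - 1 - t] for t in range(stem)):
                    continue
                loop = (j - stem + 1) - (i + stem)
                dh = ds = 0.0
                for t in range(stem - 1):
                    h, s = thermo.default_table().stack(
                        top[t:t + 2], bottom[stem - 1 - t] + bottom[stem - 2 - t])
                    dh += h
                    ds += s
                ds += 0.368 * (stem - 1) * math.log(
                    conditions.monovalent_equivalent_M())
                ds += thermo._loop_ds(loop)
                if dh < 0 and ds < 0:
                    tm = dh * 1000.0 / ds - 273.15
                    if best is None or tm > best:
                        best = tm
    return best
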