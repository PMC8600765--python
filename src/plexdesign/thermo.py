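"""Nearest-neighbour duplex thermodynamics for short DNA oligos.

Implements the unified nearest-neighbour model: duplex melting temperature
and Gibbs free energy are obtained by summing stacked-dinucleotide dH/dS
contributions (1 M NaCl reference state) plus initiation terms, then applying
a monovalent-equivalent salt correction to the entropy.  Single internal
mismatches are scored from the published mismatch stack tables; runs of two
or more adjacent mismatches are treated as unstacked (zero contribution),
which overestimates binding stability and therefore errs on the safe side
when the results feed specificity filtering.

Hairpin and heterodimer evaluation are exhaustive over stems/registers,
which is exact and fast at primer scale (<= ~60 nt including 5' tags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

R_GAS = 1.987  # cal / (mol K)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: hairpin loop initiation dG at 37 C (kcal/mol) by loop length, unified NN
#: compilation; lengths beyond the table use Jacobson-Stockmayer extrapolation.
_HAIRPIN_LOOP_DG37 = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5,
    10: 4.6, 12: 5.0, 14: 5.1, 16: 5.3, 18: 5.5, 20: 5.7, 25: 6.1, 30: 6.3,
}

_MIN_STEM = 3     # bp; shorter stems are not reported as structures
_MIN_LOOP = 3     # nt
_MIN_DIMER_RUN = 3  # bp of contiguous complementarity


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ThermoConditions:
    """Buffer and assay conditions for thermodynamic evaluation.

    Concentrations in mM except the oligo strand concentration (nM).
    ``dg_temperature_C`` is the temperature at which dG values are reported.
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 1.5
    dNTP_mM: float = 0.6
    dmso_percent: float = 0.0
    oligo_nM: float = 50.0
    dg_temperature_C: float = 37.0

    def __post_init__(self):
        for name in ("monovalent_mM", "divalent_mM", "dNTP_mM",
                     "dmso_percent", "oligo_nM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def monovalent_equivalent_M(self) -> float:
        """Effective monovalent cation concentration (mol/L).

        Divalent cations are converted with the 120*sqrt(Mg - dNTP) rule;
        dNTPs chelate Mg2+ so only the excess contributes.
        """
        free_divalent = max(self.divalent_mM - self.dNTP_mM, 0.0)
        return (self.monovalent_mM + 120.0 * math.sqrt(free_divalent)) / 1000.0


@dataclass(frozen=True)
class ThermoResult:
    """Outcome of a secondary-structure evaluation.

    When ``structure_found`` is False, ``tm_C`` and ``dg_kcal_mol`` are None
    (never spurious numbers).
    """

    structure_found: bool
    tm_C: float | None = None
    dg_kcal_mol: float | None = None
    descriptor: str = ""

    @staticmethod
    def none() -> "ThermoResult":
        return ThermoResult(False, None, None, "no structure")


class NNParameterTable:
    """Nearest-neighbour dH/dS parameters loaded from the shipped text table.

    Keys use the ``XY/WZ`` convention: top strand 5'-XY-3' over bottom strand
    3'-WZ-5'.  Lookups transparently try the 180-degree-rotated orientation.
    """

    def __init__(self, stacks, mismatches, inits):
        self.stacks = stacks
        self.mismatches = mismatches
        self.inits = inits
        for a in "ACGT":
            for b in "ACGT":
                key = f"{a}{b}/{complement(a)}{complement(b)}"
                if self._lookup(self.stacks, key) is None:
                    raise ValueError(f"incomplete WC stack table: {key}")

    @classmethod
    def load_default(cls) -> "NNParameterTable":
        text = (resources.files("plexdesign") / "data" / "nn_parameters.tsv").read_text()
        stacks, mismatches, inits = {}, {}, {}
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            kind, key, dh, ds = line.split("\t")
            entry = (float(dh), float(ds))
            if kind == "stack":
                stacks[key] = entry
            elif kind == "mismatch":
                mismatches[key] = entry
            elif kind == "init":
                inits[key] = entry
        return cls(stacks, mismatches, inits)

    @staticmethod
    def _lookup(table, key):
        if key in table:
            return table[key]
        top, bottom = key.split("/")
        rot = f"{bottom[::-1]}/{top[::-1]}"
        return table.get(rot)

    def stack(self, top: str, bottom: str):
        v = self._lookup(self.stacks, f"{top}/{bottom}")
        if v is None:
            raise KeyError(f"no WC stack {top}/{bottom}")
        return v

    def mismatch_stack(self, top: str, bottom: str):
        """Mismatch stack dH/dS, or None if the context is not tabulated."""
        return self._lookup(self.mismatches, f"{top}/{bottom}")

    def init(self, key: str):
        return self.inits.get(key, (0.0, 0.0))


_TABLE: NNParameterTable | None = None


def default_table() -> NNParameterTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = NNParameterTable.load_default()
    return _TABLE


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def _check_acgt(seq: str, what: str = "sequence") -> None:
    if not seq or any(b not in "ACGT" for b in seq):
        raise ValueError(f"{what} must be a non-empty ACGT string: {seq!r}")


def _duplex_sum(seq: str, table: NNParameterTable) -> tuple[float, float]:
    """dH (kcal/mol), dS (cal/mol/K) of seq paired with its full complement."""
    dh, ds = table.init("init")
    for end in (seq[0], seq[-1]):
        key = "init_A/T" if end in "AT" else "init_G/C"
        h, s = table.init(key)
        dh, ds = dh + h, ds + s
    for i in range(len(seq) - 1):
        top = seq[i:i + 2]
        bottom = complement(seq[i]) + complement(seq[i + 1])
        h, s = table.stack(top, bottom)
        dh, ds = dh + h, ds + s
    return dh, ds


def _salt_corrected_ds(ds: float, n_pairs: int, conditions: ThermoConditions) -> float:
    na_eq = conditions.monovalent_equivalent_M()
    return ds + 0.368 * max(n_pairs - 1, 0) * math.log(na_eq)


def _bimolecular_tm(dh: float, ds_corr: float, conditions: ThermoConditions,
                    self_complementary: bool = False) -> float:
    ct = conditions.oligo_nM * 1e-9
    k = ct if self_complementary else ct / 4.0
    tm = dh * 1000.0 / (ds_corr + R_GAS * math.log(k)) - 273.15
    return tm - 0.6 * conditions.dmso_percent


def _dg_at(dh: float, ds_corr: float, temperature_C: float) -> float:
    return dh - (temperature_C + 273.15) * ds_corr / 1000.0


def duplex_tm(seq: str, conditions: ThermoConditions | None = None,
              table: NNParameterTable | None = None) -> float:
    """Melting temperature (C) of ``seq`` against its perfect complement."""
    conditions = conditions or ThermoConditions()
    table = table or default_table()
    _check_acgt(seq)
    if len(seq) < 2:
        raise ValueError("duplex requires length >= 2")
    dh, ds = _duplex_sum(seq, table)
    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        h, s = table.init("sym")
        dh, ds = dh + h, ds + s
    ds_corr = _salt_corrected_ds(ds, len(seq), conditions)
    return _bimolecular_tm(dh, ds_corr, conditions, self_complementary=selfcomp)


def duplex_dg(seq: str, conditions: ThermoConditions | None = None,
              table: NNParameterTable | None = None) -> float:
    """dG (kcal/mol) of the perfect duplex at the reporting temperature."""
    conditions = conditions or ThermoConditions()
    return site_duplex_dG(seq, seq, conditions, table)


def site_duplex_dG(primer: str, site_seq: str,
                   conditions: ThermoConditions | None = None,
                   table: NNParameterTable | None = None) -> float:
    """dG (kcal/mol) of the primer annealed at a genomic site.

    ``site_seq`` is the genome top strand at the binding location written in
    the primer's sense, so position i of the primer pairs with the complement
    of ``site_seq[i]``; ``primer[i] == site_seq[i]`` is a Watson-Crick match.
    Isolated internal mismatches are scored from the mismatch stack table;
    adjacent mismatch runs, terminal mismatches and untabulated contexts
    contribute nothing (conservative: binding is never underestimated by a
    missing destabilisation term).  N in the site is a mismatch.
    """
    conditions = conditions or ThermoConditions()
    table = table or default_table()
    _check_acgt(primer, "primer")
    if not site_seq or any(b not in "ACGTN" for b in site_seq):
        raise ValueError(f"site sequence must be ACGTN: {site_seq!r}")
    if len(primer) != len(site_seq):
        raise ValueError("primer and site must have equal length")
    n = len(primer)
    if n < 2:
        raise ValueError("duplex requires length >= 2")

    mismatched = [primer[i] != site_seq[i] or site_seq[i] == "N" for i in range(n)]

    def isolated_internal(i: int) -> bool:
        if not (0 < i < n - 1):
            return False
        return not mismatched[i - 1] and not mismatched[i + 1]

    dh, ds = table.init("init")
    for idx in (0, n - 1):
        if not mismatched[idx]:
            key = "init_A/T" if primer[idx] in "AT" else "init_G/C"
            h, s = table.init(key)
            dh, ds = dh + h, ds + s
    for i in range(n - 1):
        a, b = mismatched[i], mismatched[i + 1]
        top = primer[i:i + 2]
        bottom = complement(site_seq[i]) + complement(site_seq[i + 1])
        if not a and not b:
            h, s = table.stack(top, bottom)
        elif a != b:
            pos = i if a else i + 1
            entry = table.mismatch_stack(top, bottom) if isolated_internal(pos) else None
            h, s = entry if entry is not None else (0.0, 0.0)
        else:
            h, s = 0.0, 0.0
        dh, ds = dh + h, ds + s
    ds_corr = _salt_corrected_ds(ds, n, conditions)
    return _dg_at(dh, ds_corr, conditions.dg_temperature_C)


def _loop_ds(loop_len: int) -> float:
    """Entropic cost (cal/mol/K, negative) of a hairpin loop, dH taken as 0."""
    if loop_len in _HAIRPIN_LOOP_DG37:
        dg37 = _HAIRPIN_LOOP_DG37[loop_len]
    elif loop_len > 30:
        dg37 = _HAIRPIN_LOOP_DG37[30] + 1.75 * R_GAS * 310.15 / 1000.0 * math.log(loop_len / 30.0)
    else:
        below = max(k for k in _HAIRPIN_LOOP_DG37 if k <= loop_len)
        above = min(k for k in _HAIRPIN_LOOP_DG37 if k >= loop_len)
        if below == above:
            dg37 = _HAIRPIN_LOOP_DG37[below]
        else:
            f = (loop_len - below) / (above - below)
            dg37 = (1 - f) * _HAIRPIN_LOOP_DG37[below] + f * _HAIRPIN_LOOP_DG37[above]
    return -dg37 * 1000.0 / 310.15


def hairpin_eval(seq: str, conditions: ThermoConditions | None = None,
                 table: NNParameterTable | None = None) -> ThermoResult:
    """Best (highest-Tm) self-folded stem-loop of a single oligo.

    Exhaustive over all stem placements and extensions; minimum loop 3 nt,
    minimum stem 3 bp.  Unimolecular, so Tm has no concentration term.
    """
    conditions = conditions or ThermoConditions()
    table = table or default_table()
    _check_acgt(seq)
    n = len(seq)
    best: ThermoResult = ThermoResult.none()
    if n < 2 * _MIN_STEM + _MIN_LOOP:
        return best
    for i in range(n):
        for j in range(n - 1, i + 2 * _MIN_STEM + _MIN_LOOP - 2, -1):
            dh, ds = 0.0, 0.0
            s = 0
            while (i + s < j - s - _MIN_LOOP
                   and seq[i + s] == complement(seq[j - s])):
                if s > 0:
                    top = seq[i + s - 1:i + s + 1]
                    bottom = seq[j - s + 1] + seq[j - s]
                    h, sv = table.stack(top, bottom)
                    dh, ds = dh + h, ds + sv
                s += 1
                if s >= _MIN_STEM:
                    loop_len = (j - s + 1) - (i + s)
                    ds_total = (_salt_corrected_ds(ds, s, conditions)
                                + _loop_ds(loop_len))
                    if dh < 0 and ds_total < 0:
                        tm = dh * 1000.0 / ds_total - 273.15
                        tm -= 0.6 * conditions.dmso_percent
                        if best.tm_C is None or tm > best.tm_C:
                            dg = _dg_at(dh, ds_total, conditions.dg_temperature_C)
                            best = ThermoResult(
                                True, tm, dg,
                                f"stem {i}..{i + s - 1}/{j - s + 1}..{j} loop {loop_len}")
    return best


def heterodimer_eval(seq1: str, seq2: str,
                     conditions: ThermoConditions | None = None,
                     table: NNParameterTable | None = None) -> ThermoResult:
    """Best inter-strand hybrid between two oligos over all ungapped registers.

    Every maximal contiguous complementary run of >= 3 bp in every register is
    scored as a bimolecular duplex; the highest-Tm run is reported.  Symmetric
    in its arguments.
    """
    conditions = conditions or ThermoConditions()
    table = table or default_table()
    _check_acgt(seq1, "seq1")
    _check_acgt(seq2, "seq2")
    n1, n2 = len(seq1), len(seq2)
    s2r = seq2[::-1]
    best: ThermoResult = ThermoResult.none()
    for shift in range(-(n2 - 1), n1):
        lo = max(0, shift)
        hi = min(n1, shift + n2)
        run_start = None
        for i in range(lo, hi + 1):
            matched = i < hi and s2r[i - shift] == complement(seq1[i])
            if matched and run_start is None:
                run_start = i
            elif not matched and run_start is not None:
                run_len = i - run_start
                if run_len >= _MIN_DIMER_RUN:
                    sub = seq1[run_start:i]
                    dh, ds = _duplex_sum(sub, table)
                    ds_corr = _salt_corrected_ds(ds, run_len, conditions)
                    tm = _bimolecular_tm(dh, ds_corr, conditions)
                    if best.tm_C is None or tm > best.tm_C:
                        dg = _dg_at(dh, ds_corr, conditions.dg_temperature_C)
                        best = ThermoResult(
                            True, tm, dg,
                            f"duplex seq1[{run_start}:{i}] shift {shift}")
                run_start = None
    return best
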