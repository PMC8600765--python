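"""Single-pair filtration: hairpin, within-pair dimer, mask, specificity.

Each filter is a pure predicate on (pair, environment); the surviving set is
therefore invariant under filter order.  The composed stage applies them in a
fixed order (hairpin -> dimer -> masked_area -> masked_site -> specificity)
and attributes each dropped pair to its first failing stage, so per-stage
counts partition the failures.

Threshold semantics are strict: a hairpin at exactly 45.0 C or a dimer at
exactly 40.0 C passes ("over 45 C" / "over 40 C").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from . import thermo
from .candidates import PrimerPair
from .genome_io import GenomeReference, MaskTrack, TargetRegion
from .oligo_align import OligoIndex, find_binding_sites, predict_amplicons
from .params import DesignParameters, FailureRecord
from .thermo import ThermoConditions


@dataclass
class FilterVerdict:
    kept: bool
    stage: str
    reason: str = ""
    metrics: dict | None = None

    def __post_init__(self):
        if not self.kept and not self.reason:
            raise ValueError("dropped verdict needs a reason")


def hairpin_filter(pair: PrimerPair, params: DesignParameters,
                   conditions: ThermoConditions | None = None) -> FilterVerdict:
    """Drop when either tagged primer folds with Tm strictly over the threshold."""
    conditions = conditions or ThermoConditions()
    worst_tm, worst_side, worst = None, None, None
    for side, seq in (("forward", pair.effective_forward()),
                      ("reverse", pair.effective_reverse())):
        res = thermo.hairpin_eval(seq, conditions)
        if res.structure_found and (worst_tm is None or res.tm_C > worst_tm):
            worst_tm, worst_side, worst = res.tm_C, side, res
    metrics = {"tm_C": worst_tm, "threshold_C": params.hairpin_tm_threshold,
               "side": worst_side,
               "descriptor": worst.descriptor if worst else "no structure"}
    if worst_tm is not None and worst_tm > params.hairpin_tm_threshold:
        return FilterVerdict(False, "hairpin",
                             f"{worst_side} hairpin Tm {worst_tm:.1f} C", metrics)
    return FilterVerdict(True, "hairpin", metrics=metrics)


def dimer_filter(pair: PrimerPair, params: DesignParameters,
                 conditions: ThermoConditions | None = None) -> FilterVerdict:
    """Drop when the tagged forward/reverse heterodimer Tm is strictly over
    the threshold."""
    conditions = conditions or ThermoConditions()
    res = thermo.heterodimer_eval(pair.effective_forward(),
                                  pair.effective_reverse(), conditions)
    metrics = {"tm_C": res.tm_C, "threshold_C": params.dimer_tm_threshold,
               "descriptor": res.descriptor}
    if res.structure_found and res.tm_C > params.dimer_tm_threshold:
        return FilterVerdict(False, "dimer", f"F/R dimer Tm {res.tm_C:.1f} C", metrics)
    return FilterVerdict(True, "dimer", metrics=metrics)


def mask_filter(pair: PrimerPair, masks: MaskTrack,
                params: DesignParameters) -> FilterVerdict:
    """Drop when the 3'-terminal window of either primer intersects a masked
    area (stage masked_area) or site (stage masked_site)."""
    w = params.three_prime_mask_window
    for primer in (pair.forward, pair.reverse):
        start, end = primer.three_prime_interval(w)
        hits = masks.area_hits(primer.chrom, start, end)
        if hits:
            return FilterVerdict(False, "masked_area",
                                 f"{primer.side} 3' end in masked area",
                                 {"interval": hits[0], "window": (start, end)})
    for primer in (pair.forward, pair.reverse):
        start, end = primer.three_prime_interval(w)
        hits = masks.site_hits(primer.chrom, start, end)
        if hits:
            return FilterVerdict(False, "masked_site",
                                 f"{primer.side} 3' end on masked site",
                                 {"interval": hits[0], "window": (start, end)})
    return FilterVerdict(True, "masked_area")


def specificity_filter(pair: PrimerPair, index: OligoIndex,
                       genome: GenomeReference, params: DesignParameters,
                       conditions: ThermoConditions | None = None,
                       targets: list[TargetRegion] | None = None) -> FilterVerdict:
    """Drop when the pair can form any off-target amplicon genome-wide.

    Side effect by design: caches the primers' binding sites on the pair
    (``forward_sites`` / ``reverse_sites``) for reuse by clustering.
    """
    conditions = conditions or ThermoConditions()
    targets = targets or []
    pair.forward_sites = find_binding_sites(pair.forward, index, genome,
                                            params, conditions)
    pair.reverse_sites = find_binding_sites(pair.reverse, index, genome,
                                            params, conditions)
    amplicons = predict_amplicons(pair.forward_sites, pair.reverse_sites,
                                  params, targets, own_target_ids={pair.target_id})
    off = [a for a in amplicons if not a.on_target]
    nonspecific = sum(1 for s in pair.forward_sites + pair.reverse_sites
                      if not s.is_intended)
    metrics = {"off_target_amplicons": len(off),
               "nonspecific_sites": nonspecific,
               "off_target": [(a.chrom, a.start, a.end, a.orientation) for a in off]}
    if off:
        return FilterVerdict(False, "specificity",
                             f"{len(off)} off-target amplicon(s)", metrics)
    return FilterVerdict(True, "specificity", metrics=metrics)


_ORDER = ("hairpin", "dimer", "mask", "specificity")


def apply_single_pair_filters(pairs_by_target: dict[str, list[PrimerPair]],
                              masks: MaskTrack, index: OligoIndex,
                              genome: GenomeReference, params: DesignParameters,
                              conditions: ThermoConditions | None = None,
                              targets: list[TargetRegion] | None = None,
                              order: tuple[str, ...] = _ORDER,
                              ) -> tuple[dict[str, list[PrimerPair]], list[FailureRecord]]:
    """Run all four filters over every candidate pair of every target.

    A pair stops at its first failing stage.  Targets left with no surviving
    pair get a target-level failure record naming the modal failing stage.
    """
    conditions = conditions or ThermoConditions()
    kept: dict[str, list[PrimerPair]] = {}
    failures: list[FailureRecord] = []
    for tid, pairs in pairs_by_target.items():
        survivors = []
        stage_count: Counter = Counter()
        for pair in pairs:
            verdict = None
            for name in order:
                if name == "hairpin":
                    verdict = hairpin_filter(pair, params, conditions)
                elif name == "dimer":
                    verdict = dimer_filter(pair, params, conditions)
                elif name == "mask":
                    verdict = mask_filter(pair, masks, params)
                elif name == "specificity":
                    verdict = specificity_filter(pair, index, genome, params,
                                                 conditions, targets)
                else:
                    raise ValueError(f"unknown filter {name!r}")
                if not verdict.kept:
                    break
            if verdict.kept:
                # make sure the site cache exists even under permuted orders
                if pair.forward_sites is None:
                    specificity_filter(pair, index, genome, params, conditions, targets)
                survivors.append(pair)
            else:
                stage_count[verdict.stage] += 1
                failures.append(FailureRecord(tid, verdict.stage, verdict.reason,
                                              verdict.metrics or {}, pair.pair_id))
        if survivors:
            kept[tid] = survivors
        elif pairs:
            modal = stage_count.most_common(1)[0][0]
            failures.append(FailureRecord(
                tid, modal, f"all {len(pairs)} candidate pairs filtered "
                f"(modal stage: {modal})",
                {"per_stage": dict(stage_count)}))
    return kept, failures
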