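"""Run-wide design parameters and the failure ledger record."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

#: Default 5' tags for two-step PCR on the Illumina platform (read-2 and
#: read-1 sequencing-primer stubs; 34 and 33 nt).
DEFAULT_TAG_FORWARD = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"
DEFAULT_TAG_REVERSE = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"

STAGES = ("design", "hairpin", "dimer", "masked_area", "masked_site",
          "specificity", "cluster")


@dataclass(frozen=True)
class DesignParameters:
    """Every threshold of the design method in one validated record.

    Boundary semantics follow the method's stated rules: a genome alignment
    counts as a binding site when it is *longer than 12 bp* (>= 13), has
    *fewer than 9* mismatches (<= 8) and *fewer than 3* mismatches in the
    3'-terminal bases (<= 2); secondary structures are rejected when their Tm
    is strictly *over* the 45 C (hairpin) / 40 C (dimer) thresholds; binding
    is flagged when dG <= -10 kcal/mol.
    """

    # amplicon and primer geometry
    product_min: int = 200
    product_max: int = 500
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 25
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    n_candidates_per_target: int = 20
    # secondary structure / binding thresholds
    hairpin_tm_threshold: float = 45.0
    dimer_tm_threshold: float = 40.0
    dg_threshold_kcal: float = -10.0
    # binding-site (specificity) rules
    min_align_len: int = 13
    max_mismatches: int = 8
    three_prime_mismatch_limit: int = 2
    three_prime_mismatch_window: int = 3
    three_prime_mask_window: int = 7
    max_amplicon_span: int = 500
    seed_k: int = 12
    # multiplex compatibility
    length_unity_bp: int = 150
    tm_unity_C: float = 5.0
    allowed_cross_false_alignments: int = 0
    # candidate ranking weights
    w_tm: float = 1.0
    w_len: float = 1.0

    def __post_init__(self):
        for lo, opt, hi in (
            (self.primer_len_min, self.primer_len_opt, self.primer_len_max),
            (self.tm_min, self.tm_opt, self.tm_max),
        ):
            if not (lo <= opt <= hi):
                raise ValueError(f"min <= opt <= max violated: {lo}, {opt}, {hi}")
        if not (0 < self.product_min <= self.product_max):
            raise ValueError("invalid product size range")
        if not (0 <= self.gc_min <= self.gc_max <= 100):
            raise ValueError("invalid GC range")
        if not (8 <= self.seed_k <= 16):
            raise ValueError("seed_k must be in [8, 16]")
        if not (0 <= self.allowed_cross_false_alignments <= 4):
            raise ValueError("allowed_cross_false_alignments must be in [0, 4]")
        for name in ("min_align_len", "max_mismatches", "three_prime_mismatch_limit",
                     "three_prime_mismatch_window", "three_prime_mask_window",
                     "max_amplicon_span", "length_unity_bp", "n_candidates_per_target"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass
class FailureRecord:
    """One entry of the failure ledger: why a target or pair dropped out."""

    target_id: str
    stage: str
    reason: str
    detail: dict = field(default_factory=dict)
    pair_id: str | None = None

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown failure stage {self.stage!r}")
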