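"""Reference genome, target and mask input handling.

All internal coordinates are 0-based half-open (BED-native).  The design
window around a target of [start, end) with maximum product size P is
[start - P + 1, end + P), clipped at chromosome bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
_AMBIGUITY = str.maketrans("RYSWKMBDHVU", "N" * 11)


@dataclass
class GenomeReference:
    """Named chromosome sequences (uppercase A/C/G/T/N) with random access."""

    chromosomes: dict[str, str]

    def __post_init__(self):
        for name, seq in self.chromosomes.items():
            if not name:
                raise ValueError("empty chromosome name")
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"invalid characters in {name!r}: {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chromosomes[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"{chrom}:{start}-{end} out of bounds (len {len(seq)})")
        return seq[start:end]

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


@dataclass(frozen=True)
class TargetRegion:
    chrom: str
    start: int
    end: int
    target_id: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid target interval {self.start}..{self.end}")
        if not self.target_id:
            raise ValueError("empty target id")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MaskTrack:
    """Masked sites (small variants) and areas (repeats etc.), kept separate
    because they produce distinct failure labels downstream."""

    sites: dict[str, IntervalTree] = field(default_factory=dict)
    areas: dict[str, IntervalTree] = field(default_factory=dict)

    def site_hits(self, chrom: str, start: int, end: int):
        return sorted((iv.begin, iv.end) for iv in
                      self.sites.get(chrom, IntervalTree()).overlap(start, end))

    def area_hits(self, chrom: str, start: int, end: int):
        return sorted((iv.begin, iv.end) for iv in
                      self.areas.get(chrom, IntervalTree()).overlap(start, end))


@dataclass(frozen=True)
class DesignWindow:
    """Genomic window in which primers for one target are designed."""

    target: TargetRegion
    window_start: int
    window_end: int
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != self.window_end - self.window_start:
            raise ValueError("window sequence length mismatch")
        if not (self.window_start <= self.target.start
                and self.target.end <= self.window_end):
            raise ValueError("window does not contain target")

    @property
    def offset(self) -> int:
        """Add to a window-local coordinate to obtain the genome coordinate."""
        return self.window_start


def load_genome(path) -> GenomeReference:
    """Read a (possibly wrapped, mixed-case) multi-FASTA reference.

    IUPAC ambiguity codes other than N are degraded to N with a warning;
    duplicate record names and empty records are hard errors.
    """
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in chroms:
            raise ValueError(f"duplicate FASTA record name {name!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {name!r}")
        cleaned = seq.translate(_AMBIGUITY)
        if cleaned != seq:
            n = sum(a != b for a, b in zip(seq, cleaned))
            log.warning("%s: %d ambiguity bases converted to N", name, n)
        chroms[name] = cleaned
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeReference(chroms)


def parse_targets(path, genome: GenomeReference) -> list[TargetRegion]:
    """Read a BED4 target list (chrom, start, end, target_id), file order kept."""
    targets: list[TargetRegion] = []
    seen: set[str] = set()
    lengths = genome.lengths
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 4 or not cols[3]:
                raise ValueError(f"{path}:{lineno}: target BED needs 4 columns "
                                 "(chrom, start, end, target_id)")
            chrom, start_s, end_s, tid = cols[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if chrom not in lengths:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"{path}:{lineno}: interval {start}..{end} invalid "
                                 f"for {chrom} (len {lengths[chrom]})")
            if tid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate target id {tid!r}")
            seen.add(tid)
            targets.append(TargetRegion(chrom, start, end, tid))
    return targets


def write_targets(targets: list[TargetRegion], path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.target_id}\n")


def _parse_bed3(path, genome: GenomeReference) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    lengths = genome.lengths
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start_s, end_s = cols[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if chrom not in lengths:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"{path}:{lineno}: interval out of bounds")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    for tree in trees.values():
        tree.merge_overlaps(strict=False)
    return trees


def parse_masks(sites_path, areas_path, genome: GenomeReference) -> MaskTrack:
    """Read optional site/area mask BEDs; absent paths give empty tracks.
    Overlapping (or bookended) intervals within a track are merged."""
    sites = _parse_bed3(sites_path, genome) if sites_path else {}
    areas = _parse_bed3(areas_path, genome) if areas_path else {}
    return MaskTrack(sites=sites, areas=areas)


def extract_design_window(genome: GenomeReference, target: TargetRegion,
                          product_max_size: int) -> DesignWindow:
    """Cut the design window [start - P + 1, end + P) around a target,
    silently clipped at chromosome bounds."""
    if product_max_size < 1:
        raise ValueError("product_max_size must be >= 1")
    length = genome.lengths[target.chrom]
    start = max(0, target.start - product_max_size + 1)
    end = min(length, target.end + product_max_size)
    return DesignWindow(target, start, end, genome.fetch(target.chrom, start, end))
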