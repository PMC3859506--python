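"""Shared domain types for the airborne-metagenome pipeline.

The atoms flowing through every stage are :class:`Read` (one shotgun read),
:class:`HitRecord` (one local-alignment match in the twelve-column tabular
dialect) and :class:`MaskInterval` (a masked region on a read).  All numeric
thresholds used anywhere in the pipeline live in :class:`PipelineConfig` so a
run is fully described by its config plus its seed.

Coordinate conventions: external hit tables are 1-based inclusive (the
convention of the tabular alignment dialect they come from); internal mask
intervals are 0-based half-open (the convention of BED).  Conversions happen
at the IO boundary, nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

KINGDOMS = ("Archaea", "Bacteria", "Eukaryota", "Viruses")
#: The seven read-level taxonomy categories (four kingdoms, reads with
#: conflicting peptide kingdoms, unidentifiable/synthetic subjects, no match).
CATEGORIES = ("Archaea", "Bacteria", "Eukaryota", "Mixed", "Viruses", "Other",
              "Unclassified")


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class Read:
    """A single nucleotide read with its sample label."""

    id: str
    seq: str
    sample: str = ""

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    def revcomp(self) -> "Read":
        return Read(self.id, revcomp(self.seq), self.sample)


@dataclass(frozen=True)
class HitRecord:
    """One local-alignment match (HSP) between a query and a subject.

    Coordinates are 1-based inclusive with ``q_start <= q_end`` and
    ``s_start <= s_end``; a match to the subject's reverse complement is
    carried in ``strand`` ("minus") rather than by swapped coordinates.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    strand: str = "plus"

    def __post_init__(self):
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0,100]")
        if self.aln_length <= 0:
            raise ValueError("aln_length must be positive")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("coordinates must be normalized (start <= end)")
        if self.strand not in ("plus", "minus"):
            raise ValueError(f"strand {self.strand!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass(frozen=True)
class MaskInterval:
    """A masked region on a read, 0-based half-open."""

    read_id: str
    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) on {self.read_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PipelineConfig:
    """Every numeric threshold used by the pipeline, with its default.

    Defaults are the values the method was defined with: an exact repeat of
    at least 25 bp flags a read as chimeric; flags propagate over matches
    with >90% identity covering >95% of the query; a read is dropped when
    more than 50% of its length is masked; the nucleotide prescreen keeps at
    most ten hits below e-value 1e-5; resistance/virulence matches need
    ≥90% identity over ≥90% of the peptide; genera under 2% abundance form
    the long tail.
    """

    min_repeat_len: int = 25
    propagate_min_identity: float = 90.0   # strict >
    propagate_min_cov: float = 95.0        # strict >, percent of query length
    mask_drop_fraction: float = 50.0       # strict >, percent of read length
    max_nt_hits: int = 10
    nt_evalue_cutoff: float = 1e-5
    stringent_identity: float = 90.0       # inclusive >=
    stringent_cov: float = 90.0            # inclusive >=
    genus_tail_cutoff: float = 2.0         # strict <, percent abundance
    # pair-pattern geometry (not stated by the method; configurable)
    pattern_min_hit_len: int = 25
    pattern_evalue_cutoff: float = 1e-5
    inverted_overlap_tolerance: int = 100  # bases between subject intervals
    # internal-repeat "reverse direction": reverse complement (the MDA
    # branch-migration product) or plain reversal
    reverse_repeat_is_revcomp: bool = True
    # replicate definition (prefix-3, identity, length-difference rule)
    replicate_prefix: int = 3
    replicate_min_identity: float = 90.0
    replicate_max_len_diff: float = 10.0   # percent of the longer read
    # DUST stand-in
    dust_window: int = 64
    dust_level: int = 20
    # repeat-library screen stand-in
    repeat_seed_k: int = 15
    repeat_min_len: int = 50
    repeat_min_identity: float = 80.0
    seed: int = 0

    def __post_init__(self):
        for name in ("propagate_min_identity", "propagate_min_cov",
                     "mask_drop_fraction", "stringent_identity",
                     "stringent_cov", "genus_tail_cutoff",
                     "replicate_min_identity", "replicate_max_len_diff",
                     "repeat_min_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0,100]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T) of a sequence.

    N and other ambiguity symbols are excluded from both numerator and
    denominator.  A sequence with no unambiguous base returns NaN (the
    undefined marker; such reads are excluded from GC summaries downstream).

    Raises ``ValueError`` on an empty sequence.
    """
    if not seq:
        raise ValueError("gc_fraction: empty sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    if denom == 0:
        return math.nan
    return gc / denom


def merge_intervals(intervals: list[MaskInterval]) -> list[MaskInterval]:
    """Merge overlapping/adjacent mask intervals (same read assumed)."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda m: (m.start, m.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = MaskInterval(last.read_id, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def masked_fraction(read_length: int, intervals: list[MaskInterval]) -> float:
    """Union length of the intervals divided by the read length.

    Intervals must lie within ``[0, read_length)``; out-of-bounds intervals
    raise ``ValueError``.
    """
    for iv in intervals:
        if iv.end > read_length:
            raise ValueError(
                f"interval [{iv.start},{iv.end}) exceeds read length {read_length}")
    union = sum(iv.length for iv in merge_intervals(intervals))
    return union / read_length
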