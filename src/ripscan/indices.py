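"""RIP dinucleotide indices, base counting and RIP-positive classification.

The mutational footprint of Repeat-Induced Point mutation (RIP) is measured
through three dinucleotide-frequency indices computed over a region of
sequence:

* **product index** ``TpA / ApT`` — RIP converts CpA (and, on the
  complementary strand, TpG) dinucleotides into TpA, so RIP-affected
  sequence is enriched for TpA relative to ApT.  Values ≥ 1.1 indicate RIP.
* **substrate index** ``(CpA + TpG) / (ApC + GpT)`` — the pathway consumes
  its preferred substrate dinucleotides; values ≤ 0.75 indicate RIP under
  the stringent setting recommended by the calibration study.
* **composite index** ``product − substrate`` — positive values indicate
  simultaneous product enrichment and substrate depletion.

GC content ``(G + C) / (G + C + A + T)`` is computed alongside, since
heavily RIP-mutated regions are strongly AT-rich.

Zero denominators yield ``None`` (an in-band "undefined", never an
exception) and an undefined index can never be RIP-positive.  Ambiguous
residues (``N`` and other IUPAC codes) are excluded from all counts;
overlapping dinucleotides touching an ambiguous base are tallied as
``skipped_pairs`` so the pair-count bookkeeping remains exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Dict, Optional

import numpy as np

from .io import SequenceRecord

__all__ = [
    "BaseCounts",
    "DinucleotideCounts",
    "RipIndices",
    "RipThresholds",
    "encode",
    "count_bases",
    "count_dinucleotides",
    "product_index",
    "substrate_index",
    "composite_index",
    "gc_content",
    "region_indices",
    "is_rip_positive",
]

# Residue codes: A=0, C=1, G=2, T=3, anything else (ambiguous) = 4.
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i

_BASES = "ACGT"
_DINUCS = ["".join(p) for p in _iterproduct(_BASES, repeat=2)]  # AA, AC, ... TT


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as uint8 codes (A=0, C=1, G=2, T=3, ambiguous=4)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


@dataclass(frozen=True)
class BaseCounts:
    """Unambiguous base counts for a region; ``skipped`` counts ambiguous residues."""

    a: int
    c: int
    g: int
    t: int
    skipped: int = 0

    @property
    def total(self) -> int:
        """Number of unambiguous bases."""
        return self.a + self.c + self.g + self.t


@dataclass(frozen=True)
class DinucleotideCounts:
    """Counts of the 16 ordered dinucleotides over unambiguous bases.

    ``skipped_pairs`` counts overlapping pairs in which at least one member
    is ambiguous, so that ``sum(counts) + skipped_pairs == region_length - 1``.
    """

    counts: Dict[str, int] = field(default_factory=dict)
    skipped_pairs: int = 0

    def __post_init__(self) -> None:
        full = {d: 0 for d in _DINUCS}
        full.update(self.counts)
        object.__setattr__(self, "counts", full)

    def __getitem__(self, dinuc: str) -> int:
        return self.counts[dinuc.upper()]

    @property
    def tpa(self) -> int:
        return self.counts["TA"]

    @property
    def apt(self) -> int:
        return self.counts["AT"]

    @property
    def cpa(self) -> int:
        return self.counts["CA"]

    @property
    def tpg(self) -> int:
        return self.counts["TG"]

    @property
    def apc(self) -> int:
        return self.counts["AC"]

    @property
    def gpt(self) -> int:
        return self.counts["GT"]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class RipIndices:
    """The three RIP indices plus GC content for one region.

    ``None`` marks an undefined value (zero denominator, e.g. an AT-free or
    all-ambiguous window).
    """

    product: Optional[float]
    substrate: Optional[float]
    composite: Optional[float]
    gc: Optional[float]


@dataclass(frozen=True)
class RipThresholds:
    """User-tunable cut-offs and window geometry.

    Defaults follow the stringent recommendation from random-sequence
    calibration: product ≥ 1.1, substrate ≤ 0.75, composite > 0, on
    1,000 bp windows advanced in 500 bp steps, with large RIP-affected
    regions (LRARs) requiring ≥ 7 consecutive positive windows spanning
    ≥ 4,000 bp.
    """

    product_min: float = 1.1
    substrate_max: float = 0.75
    composite_min: float = 0.0
    window: int = 1000
    step: int = 500
    lrar_min_windows: int = 7
    lrar_min_span: int = 4000

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError(f"window must be >= 2, got {self.window}")
        if not (1 <= self.step <= self.window):
            raise ValueError(f"step must satisfy 1 <= step <= window, got step={self.step}, window={self.window}")
        if self.lrar_min_windows < 1:
            raise ValueError(f"lrar_min_windows must be >= 1, got {self.lrar_min_windows}")
        if self.lrar_min_span < self.window:
            raise ValueError(
                f"lrar_min_span ({self.lrar_min_span}) must be >= window ({self.window})"
            )


def _check_interval(record: SequenceRecord, start: int, end: int) -> None:
    if not (0 <= start < end <= record.length):
        raise ValueError(
            f"interval [{start}, {end}) out of range for {record.id!r} of length {record.length}"
        )


def count_bases(record: SequenceRecord, start: int = 0, end: Optional[int] = None) -> BaseCounts:
    """Count A/C/G/T within the half-open interval ``[start, end)``.

    Non-ACGT residues are tallied in ``skipped``.
    """
    if end is None:
        end = record.length
    _check_interval(record, start, end)
    region = record.residues[start:end]
    a = region.count("A")
    c = region.count("C")
    g = region.count("G")
    t = region.count("T")
    return BaseCounts(a=a, c=c, g=g, t=t, skipped=len(region) - a - c - g - t)


def count_dinucleotides(
    record: SequenceRecord, start: int = 0, end: Optional[int] = None
) -> DinucleotideCounts:
    """Count all 16 overlapping ordered dinucleotides within ``[start, end)``.

    A pair at positions (i, i+1) with either member ambiguous is counted in
    ``skipped_pairs`` instead.
    """
    if end is None:
        end = record.length
    _check_interval(record, start, end)
    codes = encode(record.residues[start:end])
    if codes.size < 2:
        return DinucleotideCounts(counts={}, skipped_pairs=0)
    left, right = codes[:-1], codes[1:]
    valid = (left < 4) & (right < 4)
    pair_codes = (left[valid].astype(np.intp) << 2) | right[valid]
    tally = np.bincount(pair_codes, minlength=16)
    counts = {d: int(tally[i]) for i, d in enumerate(_DINUCS)}
    return DinucleotideCounts(counts=counts, skipped_pairs=int(valid.size - valid.sum()))


def product_index(d: DinucleotideCounts) -> Optional[float]:
    """RIP product index TpA/ApT; ``None`` when no ApT pairs exist."""
    if d.apt == 0:
        return None
    return d.tpa / d.apt


def substrate_index(d: DinucleotideCounts) -> Optional[float]:
    """RIP substrate index (CpA+TpG)/(ApC+GpT); ``None`` when the denominator is 0."""
    denom = d.apc + d.gpt
    if denom == 0:
        return None
    return (d.cpa + d.tpg) / denom


def composite_index(product: Optional[float], substrate: Optional[float]) -> Optional[float]:
    """Composite index: product − substrate; undefined if either input is."""
    if product is None or substrate is None:
        return None
    return product - substrate


def gc_content(b: BaseCounts) -> Optional[float]:
    """GC fraction (G+C)/(A+C+G+T); ``None`` for an all-ambiguous region."""
    if b.total == 0:
        return None
    return (b.g + b.c) / b.total


def region_indices(record: SequenceRecord, start: int = 0, end: Optional[int] = None) -> RipIndices:
    """All three RIP indices plus GC content for one region in a single call."""
    d = count_dinucleotides(record, start, end)
    b = count_bases(record, start, end)
    p = product_index(d)
    s = substrate_index(d)
    return RipIndices(product=p, substrate=s, composite=composite_index(p, s), gc=gc_content(b))


def is_rip_positive(idx: RipIndices, th: RipThresholds) -> bool:
    """A region is RIP-positive iff all three indices are defined and each
    signals RIP: product ≥ product_min, substrate ≤ substrate_max,
    composite > composite_min."""
    if idx.product is None or idx.substrate is None or idx.composite is None:
        return False
    return (
        idx.product >= th.product_min
        and idx.substrate <= th.substrate_max
        and idx.composite > th.composite_min
    )
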