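"""Random-sequence simulation for false-positive calibration, and synthetic
genome fixtures with planted RIP-like blocks.

The calibration study asks how often a RIP scanner flags i.i.d. random
sequence as RIP-affected, as a function of base composition and threshold
stringency: sequences are drawn with P(G) = P(C) = gc/2 and
P(A) = P(T) = (1 − gc)/2, scanned with the standard sliding window, and
classified under a full factorial grid of product/substrate cut-offs.
Under this i.i.d. model every index has expectation near 1 for long
windows, whatever the GC level, so any flagged window is a false positive
by construction.

The fixture generator plants RIP-like blocks into an otherwise random
genome by emulating the mutation process itself: within a block, the C of
each CpA dinucleotide and the G of each TpG dinucleotide (a CpA on the
complementary strand) are replaced by T and A respectively with a fixed
per-site probability.  This enriches TpA while depleting CpA/TpG and GC —
exactly the footprint the indices are designed to detect — and leaves the
background composition untouched, so the true block coordinates form a
ground truth for recall tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .indices import RipThresholds
from .io import SequenceRecord
from .lrar import _runs
from .windows import positive_mask, window_arrays_from_codes

__all__ = [
    "SimulationSpec",
    "FixtureSpec",
    "random_sequence",
    "run_calibration",
    "make_fixture",
    "CALIBRATION_COLUMNS",
]

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

CALIBRATION_COLUMNS = ["gc_level", "product_min", "substrate_max", "n_flagged", "mean_pct", "n_lrars"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the calibration sweep.

    Defaults reproduce the full study design: nine GC levels from 10% to
    90%, 100 replicate sequences of 1 Mbp per level, and a 4 × 4 grid of
    product/substrate cut-offs.  ``replicates_per_level`` can be lowered
    for a desk-scale run.
    """

    gc_levels: Sequence[float] = tuple(round(0.1 * k, 1) for k in range(1, 10))
    replicates_per_level: int = 100
    seq_length: int = 1_000_000
    seed: int = 0
    product_grid: Sequence[float] = (1.1, 1.15, 1.2, 1.25)
    substrate_grid: Sequence[float] = (0.75, 0.8, 0.85, 0.9)

    def __post_init__(self) -> None:
        if not self.gc_levels or not self.product_grid or not self.substrate_grid:
            raise ValueError("gc_levels, product_grid and substrate_grid must be non-empty")
        if any(not (0 < g < 1) for g in self.gc_levels):
            raise ValueError("every GC level must lie in (0, 1)")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    """A synthetic multi-contig genome with planted RIP-like blocks.

    ``planted_blocks`` is a list of (contig_index, start, end) half-open
    intervals; blocks on one contig must not overlap.
    """

    n_contigs: int = 1
    contig_length: int = 100_000
    planted_blocks: Sequence[Tuple[int, int, int]] = field(default_factory=tuple)
    seed: int = 0
    background_gc: float = 0.5
    mutation_rate: float = 0.9  # per-site probability of the C→T / G→A replacement

    def __post_init__(self) -> None:
        per_contig: dict = {}
        for contig, start, end in self.planted_blocks:
            if not (0 <= contig < self.n_contigs):
                raise ValueError(f"block contig index {contig} out of range")
            if not (0 <= start < end <= self.contig_length):
                raise ValueError(f"block [{start}, {end}) outside contig of length {self.contig_length}")
            per_contig.setdefault(contig, []).append((start, end))
        for contig, blocks in per_contig.items():
            blocks.sort()
            for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping blocks on contig {contig}: [{s0},{e0}) and [{s1},{e1})")
        if not (0 < self.background_gc < 1):
            raise ValueError("background_gc must lie in (0, 1)")
        if not (0 < self.mutation_rate <= 1):
            raise ValueError("mutation_rate must lie in (0, 1]")


def _random_codes(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. base codes with P(G)=P(C)=gc/2 and P(A)=P(T)=(1−gc)/2."""
    if not (0 < gc < 1):
        raise ValueError(f"gc must lie in (0, 1), got {gc}")
    at = (1 - gc) / 2
    cum = np.array([at, at + gc / 2, at + gc, 1.0])  # A, C, G, T
    return np.searchsorted(cum, rng.random(length), side="right").astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def random_sequence(length: int, gc: float, rng: np.random.Generator, seq_id: str = "random") -> SequenceRecord:
    """One i.i.d. random sequence at the requested GC content.

    Deterministic given the generator state.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    codes = _random_codes(length, gc, rng)
    return SequenceRecord(id=seq_id, description=f"iid random sequence gc={gc}", residues=_codes_to_str(codes))


def _count_lrars(mask: np.ndarray, starts: np.ndarray, ends: np.ndarray, th: RipThresholds) -> int:
    n_lrars = 0
    for i0, i1 in _runs(mask):
        n = i1 - i0 + 1
        if n >= th.lrar_min_windows and ends[i1] - starts[i0] >= th.lrar_min_span:
            n_lrars += 1
    return n_lrars


def run_calibration(spec: SimulationSpec, base: RipThresholds = RipThresholds()) -> pd.DataFrame:
    """Run the false-positive calibration sweep.

    Each replicate sequence is generated once and scanned once; the full
    product × substrate threshold grid is then applied to the same window
    metrics, mirroring a study in which one simulated data set is analysed
    at every stringency level.  A sequence is "flagged" in a cell iff at
    least one window is RIP-positive there; LRARs are counted with the
    chain criteria of ``base``.

    Returns a tidy table with one row per (gc_level, product_min,
    substrate_max) cell: ``n_flagged`` (replicates with ≥ 1 positive
    window), ``mean_pct`` (mean percentage of positive windows across
    replicates) and ``n_lrars`` (total LRARs across replicates).
    """
    if spec.seq_length < base.window:
        raise ValueError("seq_length must be at least one window")
    rng = np.random.default_rng(spec.seed)
    cells = [(p, s) for p in spec.product_grid for s in spec.substrate_grid]
    n_flagged = {c: np.zeros(len(spec.gc_levels), dtype=int) for c in cells}
    pct_sum = {c: np.zeros(len(spec.gc_levels)) for c in cells}
    n_lrars = {c: np.zeros(len(spec.gc_levels), dtype=int) for c in cells}

    for gi, gc in enumerate(spec.gc_levels):
        for _ in range(spec.replicates_per_level):
            codes = _random_codes(spec.seq_length, gc, rng)
            arrays = window_arrays_from_codes(codes, base)
            n_windows = arrays.starts.size
            for p, s in cells:
                th = RipThresholds(
                    product_min=p,
                    substrate_max=s,
                    composite_min=base.composite_min,
                    window=base.window,
                    step=base.step,
                    lrar_min_windows=base.lrar_min_windows,
                    lrar_min_span=base.lrar_min_span,
                )
                mask = positive_mask(arrays, th)
                n_pos = int(mask.sum())
                if n_pos:
                    n_flagged[(p, s)][gi] += 1
                    pct_sum[(p, s)][gi] += 100.0 * n_pos / n_windows
                    n_lrars[(p, s)][gi] += _count_lrars(mask, arrays.starts, arrays.ends, th)

    rows = []
    for gi, gc in enumerate(spec.gc_levels):
        for p, s in cells:
            rows.append(
                {
                    "gc_level": gc,
                    "product_min": p,
                    "substrate_max": s,
                    "n_flagged": int(n_flagged[(p, s)][gi]),
                    "mean_pct": pct_sum[(p, s)][gi] / spec.replicates_per_level,
                    "n_lrars": int(n_lrars[(p, s)][gi]),
                }
            )
    return pd.DataFrame(rows, columns=CALIBRATION_COLUMNS)


def _rip_mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply one round of RIP-style mutation to a block of base codes.

    The C of every CpA and the G of every TpG (the same site read on the
    complementary strand) are replaced, independently with probability
    ``rate``, by T and A respectively.
    """
    out = codes.copy()
    left, right = codes[:-1], codes[1:]
    cpa = np.flatnonzero((left == 1) & (right == 0))       # C of CpA → T
    tpg = np.flatnonzero((left == 3) & (right == 2)) + 1   # G of TpG → A
    out[cpa[rng.random(cpa.size) < rate]] = 3
    out[tpg[rng.random(tpg.size) < rate]] = 0
    return out


def make_fixture(spec: FixtureSpec) -> Tuple[List[SequenceRecord], pd.DataFrame]:
    """Generate a synthetic genome with planted RIP-like blocks.

    Returns the contig records plus a truth table (seq_id, start, end) of
    the planted intervals.  Background sequence is i.i.d. at
    ``background_gc``; inside each block the RIP-style replacement drives
    the product index well above and the substrate index well below the
    default cut-offs in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    records: List[SequenceRecord] = []
    truth_rows = []
    for ci in range(spec.n_contigs):
        codes = _random_codes(spec.contig_length, spec.background_gc, rng)
        seq_id = f"contig_{ci}"
        for contig, start, end in spec.planted_blocks:
            if contig != ci:
                continue
            codes[start:end] = _rip_mutate(codes[start:end], spec.mutation_rate, rng)
            truth_rows.append({"seq_id": seq_id, "start": start, "end": end})
        records.append(
            SequenceRecord(
                id=seq_id,
                description=f"synthetic fixture contig (background_gc={spec.background_gc})",
                residues=_codes_to_str(codes),
            )
        )
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "start", "end"])
    return records, truth
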