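"""Per-sequence summaries and the genome-wide RIP profile.

The genome-wide extent of RIP is quantified window-wise: the percentage of
RIP-positive windows among all windows investigated.  The profile also
aggregates LRAR statistics (count, mean/total size, mean GC and mean index
values, each as the unweighted mean of per-LRAR means) and the pooled GC
content of the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import pandas as pd

from .indices import count_bases, gc_content
from .io import SequenceRecord

__all__ = ["SequenceSummary", "GenomeProfile", "summarize_sequence", "summarize_sequences", "summarize_genome"]


@dataclass(frozen=True)
class SequenceSummary:
    """RIP summary for one sequence (chromosome/contig)."""

    seq_id: str
    length: int
    n_windows: int
    n_positive: int
    pct_rip: float  # percent of windows that are RIP-positive
    gc: Optional[float]  # whole-sequence GC fraction


@dataclass(frozen=True)
class GenomeProfile:
    """Assembly-level RIP profile.

    LRAR means are unweighted means of per-LRAR means and are ``None`` when
    no LRAR was detected.
    """

    total_size: int
    total_windows: int
    genome_gc: Optional[float]
    n_positive: int
    pct_rip: float
    n_lrars: int
    sum_lrar_size: int
    mean_lrar_size: Optional[float]
    mean_lrar_gc: Optional[float]
    mean_lrar_product: Optional[float]
    mean_lrar_substrate: Optional[float]
    mean_lrar_composite: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        """Two-column statistic/value table for reporting."""
        gc_pct = None if self.genome_gc is None else 100 * self.genome_gc
        lrar_gc_pct = None if self.mean_lrar_gc is None else 100 * self.mean_lrar_gc
        rows = [
            ("genome_size_bp", self.total_size),
            ("total_windows", self.total_windows),
            ("genome_gc_pct", gc_pct),
            ("rip_positive_windows", self.n_positive),
            ("genome_rip_pct", self.pct_rip),
            ("n_lrars", self.n_lrars),
            ("mean_lrar_size_bp", self.mean_lrar_size),
            ("mean_lrar_gc_pct", lrar_gc_pct),
            ("sum_lrar_size_bp", self.sum_lrar_size),
            ("mean_lrar_product_index", self.mean_lrar_product),
            ("mean_lrar_substrate_index", self.mean_lrar_substrate),
            ("mean_lrar_composite_index", self.mean_lrar_composite),
        ]
        # object dtype keeps counts integral next to float statistics
        return pd.DataFrame(
            {"statistic": [k for k, _ in rows], "value": pd.Series([v for _, v in rows], dtype=object)}
        )


def summarize_sequence(record: SequenceRecord, windows: pd.DataFrame) -> SequenceSummary:
    """Summarize one sequence from its window table.

    ``pct_rip`` is 100 · positive windows / windows investigated (0 when the
    sequence was too short to produce any window); GC is computed over the
    whole record, not averaged over windows.
    """
    if len(windows) and set(windows["seq_id"].unique()) != {record.id}:
        raise ValueError(f"window table does not belong to record {record.id!r}")
    n_windows = len(windows)
    n_positive = int(windows["positive"].sum()) if n_windows else 0
    pct = 100.0 * n_positive / n_windows if n_windows else 0.0
    return SequenceSummary(
        seq_id=record.id,
        length=record.length,
        n_windows=n_windows,
        n_positive=n_positive,
        pct_rip=pct,
        gc=gc_content(count_bases(record)),
    )


def summarize_sequences(records: Iterable[SequenceRecord], scan_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sequence summary table across a whole scan."""
    rows = []
    for rec in records:
        windows = scan_table[scan_table["seq_id"] == rec.id]
        s = summarize_sequence(rec, windows)
        rows.append(
            {
                "seq_id": s.seq_id,
                "length": s.length,
                "n_windows": s.n_windows,
                "n_positive": s.n_positive,
                "pct_rip": s.pct_rip,
                "gc_pct": None if s.gc is None else 100 * s.gc,
            }
        )
    return pd.DataFrame(rows, columns=["seq_id", "length", "n_windows", "n_positive", "pct_rip", "gc_pct"])


def summarize_genome(
    records: Iterable[SequenceRecord],
    scan_table: pd.DataFrame,
    lrar_table: pd.DataFrame,
) -> GenomeProfile:
    """Aggregate a scan and its LRARs into the genome-wide RIP profile.

    Genome GC is a single pooled ratio over all unambiguous bases of all
    records (not a mean of window GCs).
    """
    records = list(records)
    total_size = sum(r.length for r in records)
    a = c = g = t = 0
    for r in records:
        b = count_bases(r)
        a, c, g, t = a + b.a, c + b.c, g + b.g, t + b.t
    acgt = a + c + g + t
    genome_gc = (g + c) / acgt if acgt else None

    total_windows = len(scan_table)
    n_positive = int(scan_table["positive"].sum()) if total_windows else 0
    pct_rip = 100.0 * n_positive / total_windows if total_windows else 0.0

    n_lrars = len(lrar_table)
    if n_lrars:
        sum_size = int(lrar_table["size"].sum())
        profile = GenomeProfile(
            total_size=total_size,
            total_windows=total_windows,
            genome_gc=genome_gc,
            n_positive=n_positive,
            pct_rip=pct_rip,
            n_lrars=n_lrars,
            sum_lrar_size=sum_size,
            mean_lrar_size=sum_size / n_lrars,
            mean_lrar_gc=float(lrar_table["gc"].mean()),
            mean_lrar_product=float(lrar_table["product"].mean()),
            mean_lrar_substrate=float(lrar_table["substrate"].mean()),
            mean_lrar_composite=float(lrar_table["composite"].mean()),
        )
    else:
        profile = GenomeProfile(
            total_size=total_size,
            total_windows=total_windows,
            genome_gc=genome_gc,
            n_positive=n_positive,
            pct_rip=pct_rip,
            n_lrars=0,
            sum_lrar_size=0,
            mean_lrar_size=None,
            mean_lrar_gc=None,
            mean_lrar_product=None,
            mean_lrar_substrate=None,
            mean_lrar_composite=None,
        )
    return profile
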