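"""Detection of Large RIP Affected Regions (LRARs).

An LRAR is a maximal run of consecutive RIP-positive windows — an "index
chain" — that is long enough in both window count and genomic span.  With
the default geometry (1,000 bp windows, 500 bp step) the default criteria
of ≥ 7 consecutive positive windows spanning ≥ 4,000 bp mean an interior
LRAR of n windows covers exactly (n − 1)·step + window bp.

"Consecutive" means adjacent window ordinals: a single non-positive window
breaks the chain.  The reported end coordinate is the last window's nominal
end (start + window), clipped at the sequence end; per-LRAR statistics are
unweighted means over the member windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .indices import RipThresholds

__all__ = ["Lrar", "detect_lrars", "lrar_statistics", "find_lrars", "LRAR_COLUMNS"]

LRAR_COLUMNS = [
    "seq_id", "lrar", "start", "end", "size", "n_windows",
    "product", "substrate", "composite", "gc",
]


@dataclass(frozen=True)
class Lrar:
    """One detected Large RIP Affected Region."""

    seq_id: str
    start: int
    end: int
    n_windows: int
    mean_product: float
    mean_substrate: float
    mean_composite: float
    mean_gc: float

    @property
    def size(self) -> int:
        return self.end - self.start


def _runs(mask: np.ndarray) -> List[tuple]:
    """Maximal runs of True as (first_index, last_index) inclusive pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def lrar_statistics(run: pd.DataFrame) -> Lrar:
    """Build an :class:`Lrar` from one run of RIP-positive windows.

    The run must be non-empty and all-positive; positivity guarantees every
    index is defined, so the unweighted means are always finite.
    """
    if len(run) == 0:
        raise ValueError("empty window run")
    if not bool(run["positive"].all()):
        raise ValueError("run contains non-positive windows")
    return Lrar(
        seq_id=str(run["seq_id"].iloc[0]),
        start=int(run["start"].iloc[0]),
        end=int(run["end"].iloc[-1]),
        n_windows=len(run),
        mean_product=float(run["product"].mean()),
        mean_substrate=float(run["substrate"].mean()),
        mean_composite=float(run["composite"].mean()),
        mean_gc=float(run["gc"].mean()),
    )


def detect_lrars(windows: pd.DataFrame, th: RipThresholds) -> List[Lrar]:
    """Detect LRARs in the (sorted) window table of a single sequence.

    A maximal run of consecutive positive windows is reported iff its
    length is ≥ ``th.lrar_min_windows`` and its genomic span is
    ≥ ``th.lrar_min_span``.
    """
    if len(windows) == 0:
        return []
    if windows["seq_id"].nunique() > 1:
        raise ValueError("detect_lrars expects windows from a single sequence; use find_lrars")
    mask = windows["positive"].to_numpy(dtype=bool)
    out = []
    for i0, i1 in _runs(mask):
        n = i1 - i0 + 1
        if n < th.lrar_min_windows:
            continue
        run = windows.iloc[i0:i1 + 1]
        lrar = lrar_statistics(run)
        if lrar.size < th.lrar_min_span:
            continue
        out.append(lrar)
    return out


def find_lrars(scan_table: pd.DataFrame, th: RipThresholds) -> pd.DataFrame:
    """Detect LRARs across a whole scan table (all sequences).

    Returns a tidy table mirroring the per-genome LRAR report: seq_id,
    per-sequence LRAR ordinal (1-based), start, end, size, n_windows and
    the mean product/substrate/composite indices and GC fraction.
    """
    rows = []
    if len(scan_table) > 0:
        for seq_id, group in scan_table.groupby("seq_id", sort=False):
            for ordinal, lrar in enumerate(detect_lrars(group.reset_index(drop=True), th), start=1):
                rows.append(
                    {
                        "seq_id": seq_id,
                        "lrar": ordinal,
                        "start": lrar.start,
                        "end": lrar.end,
                        "size": lrar.size,
                        "n_windows": lrar.n_windows,
                        "product": lrar.mean_product,
                        "substrate": lrar.mean_substrate,
                        "composite": lrar.mean_composite,
                        "gc": lrar.mean_gc,
                    }
                )
    if not rows:
        dtypes = {c: (str if c == "seq_id" else np.int64 if c in
                      ("lrar", "start", "end", "size", "n_windows") else np.float64)
                  for c in LRAR_COLUMNS}
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in dtypes.items()})
    return pd.DataFrame(rows, columns=LRAR_COLUMNS)
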