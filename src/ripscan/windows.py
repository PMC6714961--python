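"""Sliding-window enumeration and per-window RIP metrics.

A window of ``window`` bp is advanced in ``step`` bp increments along each
sequence independently (windows never span record boundaries).  A start
``s`` is emitted iff ``s + step <= length``, so a sequence of length L
yields exactly ``floor(L / step)`` windows, the last of which may be
truncated at the sequence end.  Coordinates are 0-based, half-open.

Per-window counting is done with prefix sums over base- and
dinucleotide-indicator arrays, so a whole-genome scan is O(genome size)
regardless of window overlap.  In the resulting tables an undefined index
(zero denominator) is carried as NaN; the scalar API in
:mod:`ripscan.indices` uses ``None`` for the same states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from .indices import RipIndices, RipThresholds, encode
from .io import SequenceRecord

__all__ = [
    "WindowMetrics",
    "WindowArrays",
    "window_bounds",
    "window_arrays",
    "positive_mask",
    "enumerate_windows",
    "scan",
]

logger = logging.getLogger(__name__)

SCAN_COLUMNS = ["seq_id", "index", "start", "end", "product", "substrate", "composite", "gc", "positive"]


@dataclass(frozen=True)
class WindowMetrics:
    """Metrics for a single sliding window."""

    seq_id: str
    index: int  # 0-based window ordinal within its sequence
    start: int  # 0-based inclusive
    end: int    # exclusive; may be truncated at the sequence end
    indices: RipIndices
    positive: bool


class WindowArrays(NamedTuple):
    """Column-wise window metrics for one sequence (NaN marks undefined)."""

    starts: np.ndarray
    ends: np.ndarray
    product: np.ndarray
    substrate: np.ndarray
    composite: np.ndarray
    gc: np.ndarray


def window_bounds(length: int, window: int, step: int) -> Tuple[np.ndarray, np.ndarray]:
    """Window start/end coordinates for a sequence of the given length.

    Returns empty arrays when ``length < step``.
    """
    if length < step:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    n_windows = length // step
    starts = np.arange(n_windows, dtype=np.int64) * step
    ends = np.minimum(starts + window, length)
    return starts, ends


def _pair_prefix(pair_codes: np.ndarray, code: int) -> np.ndarray:
    cs = np.zeros(pair_codes.size + 1, dtype=np.int64)
    np.cumsum(pair_codes == code, out=cs[1:])
    return cs


def window_arrays(record: SequenceRecord, th: RipThresholds) -> WindowArrays:
    """Compute per-window indices for one sequence as dense arrays.

    Equivalent to calling :func:`ripscan.indices.region_indices` on each
    window, but in a single pass over the sequence.
    """
    codes = encode(record.residues)
    return window_arrays_from_codes(codes, th)


def window_arrays_from_codes(codes: np.ndarray, th: RipThresholds) -> WindowArrays:
    """As :func:`window_arrays`, starting from an already-encoded sequence."""
    n = codes.size
    starts, ends = window_bounds(n, th.window, th.step)
    if starts.size == 0:
        empty = np.empty(0)
        return WindowArrays(starts, ends, empty, empty, empty, empty)

    # base-count prefix sums: counts over [s, e) = cs[e] - cs[s]
    base_cs = np.zeros((4, n + 1), dtype=np.int64)
    for b in range(4):
        np.cumsum(codes == b, out=base_cs[b, 1:])

    # dinucleotide prefix sums over pair positions i in [0, n-2]; a pair is
    # skipped (counted nowhere) if either member is ambiguous
    left = codes[:-1].astype(np.int16)
    right = codes[1:].astype(np.int16)
    pair_codes = np.where((left < 4) & (right < 4), (left << 2) | right, np.int16(16))
    # codes: A=0 C=1 G=2 T=3 → TA=12, AT=3, CA=4, TG=14, AC=1, GT=11
    tpa_cs = _pair_prefix(pair_codes, 12)
    apt_cs = _pair_prefix(pair_codes, 3)
    ca_tg_cs = _pair_prefix(pair_codes, 4) + _pair_prefix(pair_codes, 14)
    ac_gt_cs = _pair_prefix(pair_codes, 1) + _pair_prefix(pair_codes, 11)

    # pairs fully inside [s, e) occupy pair positions [s, e-1)
    pe = ends - 1
    tpa = (tpa_cs[pe] - tpa_cs[starts]).astype(np.float64)
    apt = (apt_cs[pe] - apt_cs[starts]).astype(np.float64)
    substrate_num = (ca_tg_cs[pe] - ca_tg_cs[starts]).astype(np.float64)
    substrate_den = (ac_gt_cs[pe] - ac_gt_cs[starts]).astype(np.float64)

    a = base_cs[0, ends] - base_cs[0, starts]
    c = base_cs[1, ends] - base_cs[1, starts]
    g = base_cs[2, ends] - base_cs[2, starts]
    t = base_cs[3, ends] - base_cs[3, starts]
    total = (a + c + g + t).astype(np.float64)

    with np.errstate(divide="ignore", invalid="ignore"):
        product = np.where(apt > 0, tpa / apt, np.nan)
        substrate = np.where(substrate_den > 0, substrate_num / substrate_den, np.nan)
        gc = np.where(total > 0, (g + c) / total, np.nan)
    composite = product - substrate
    return WindowArrays(starts, ends, product, substrate, composite, gc)


def positive_mask(arrays: WindowArrays, th: RipThresholds) -> np.ndarray:
    """Boolean RIP-positivity per window; NaN indices are never positive."""
    with np.errstate(invalid="ignore"):
        return (
            (arrays.product >= th.product_min)
            & (arrays.substrate <= th.substrate_max)
            & (arrays.composite > th.composite_min)
        )


def _opt(x: float) -> Optional[float]:
    return None if np.isnan(x) else float(x)


def enumerate_windows(record: SequenceRecord, th: RipThresholds) -> List[WindowMetrics]:
    """Enumerate all sliding windows of one sequence with metrics attached.

    A record shorter than ``step`` yields an empty list (with a logged
    warning) rather than an error.
    """
    if record.length < th.step:
        logger.warning(
            "sequence %r (%d bp) is shorter than the step size (%d bp); no windows emitted",
            record.id, record.length, th.step,
        )
        return []
    arrays = window_arrays(record, th)
    pos = positive_mask(arrays, th)
    out = []
    for i in range(arrays.starts.size):
        idx = RipIndices(
            product=_opt(arrays.product[i]),
            substrate=_opt(arrays.substrate[i]),
            composite=_opt(arrays.composite[i]),
            gc=_opt(arrays.gc[i]),
        )
        out.append(
            WindowMetrics(
                seq_id=record.id,
                index=i,
                start=int(arrays.starts[i]),
                end=int(arrays.ends[i]),
                indices=idx,
                positive=bool(pos[i]),
            )
        )
    return out


def scan(records: Iterable[SequenceRecord], th: RipThresholds) -> pd.DataFrame:
    """Scan a set of sequences and return one tidy window table.

    Columns: seq_id, index (per-sequence ordinal restarting at 0), start,
    end, product, substrate, composite, gc, positive.  Output is fully
    deterministic for a given input and thresholds.
    """
    frames = []
    for rec in records:
        if rec.length < th.step:
            logger.warning(
                "sequence %r (%d bp) is shorter than the step size (%d bp); no windows emitted",
                rec.id, rec.length, th.step,
            )
            continue
        arrays = window_arrays(rec, th)
        pos = positive_mask(arrays, th)
        frames.append(
            pd.DataFrame(
                {
                    "seq_id": rec.id,
                    "index": np.arange(arrays.starts.size, dtype=np.int64),
                    "start": arrays.starts,
                    "end": arrays.ends,
                    "product": arrays.product,
                    "substrate": arrays.substrate,
                    "composite": arrays.composite,
                    "gc": arrays.gc,
                    "positive": pos,
                }
            )
        )
    if not frames:
        dtypes = {c: (str if c == "seq_id" else bool if c == "positive" else np.int64
                      if c in ("index", "start", "end") else np.float64)
                  for c in SCAN_COLUMNS}
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in dtypes.items()})
    return pd.concat(frames, ignore_index=True)
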