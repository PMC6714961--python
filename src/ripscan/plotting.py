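"""Fine-scale plots of RIP index tracks and GC content.

One panel traces the product, substrate and composite indices against
window start position, with horizontal guide lines at the configured
cut-offs; an optional second panel shows per-window GC content as bars.
"""

from __future__ import annotations

import os
from typing import Optional, Tuple, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .indices import RipThresholds

__all__ = ["plot_indices"]


def plot_indices(
    windows: pd.DataFrame,
    th: RipThresholds,
    out_path: Union[str, os.PathLike],
    region: Optional[Tuple[int, int]] = None,
    gc_panel: bool = True,
    title: Optional[str] = None,
) -> None:
    """Render the index tracks of one sequence's window table to a PNG.

    Parameters
    ----------
    windows:
        Window table for a single sequence (as produced by
        :func:`ripscan.windows.scan`).
    region:
        Optional (start, end) bp interval restricting the plotted windows;
        must intersect the scanned range.
    gc_panel:
        Add a bar panel of per-window GC percentage below the index panel.
    """
    if windows["seq_id"].nunique() != 1:
        raise ValueError("plot_indices expects windows from a single sequence")
    data = windows
    if region is not None:
        lo, hi = region
        max_end = int(windows["end"].max())
        if lo < 0 or hi > max_end or lo >= hi:
            raise ValueError(f"plot range [{lo}, {hi}) outside scanned bounds [0, {max_end})")
        data = windows[(windows["start"] >= lo) & (windows["start"] < hi)]
        if len(data) == 0:
            raise ValueError(f"no windows start within [{lo}, {hi})")

    nrows = 2 if gc_panel else 1
    fig, axes = plt.subplots(
        nrows, 1, figsize=(10, 3.2 * nrows), sharex=True, squeeze=False,
        gridspec_kw={"height_ratios": [2, 1] if gc_panel else [1]},
    )
    ax = axes[0, 0]
    x = data["start"]
    ax.plot(x, data["product"], color="forestgreen", label="product (TpA/ApT)")
    ax.plot(x, data["substrate"], color="goldenrod", label="substrate ((CpA+TpG)/(ApC+GpT))")
    ax.plot(x, data["composite"], color="firebrick", label="composite")
    ax.axhline(th.product_min, color="forestgreen", ls="--", lw=0.8, alpha=0.7)
    ax.axhline(th.substrate_max, color="goldenrod", ls="--", lw=0.8, alpha=0.7)
    ax.axhline(th.composite_min, color="firebrick", ls="--", lw=0.8, alpha=0.7)
    ax.set_ylabel("RIP index value")
    ax.legend(fontsize=8, loc="upper right")
    seq_id = data["seq_id"].iloc[0]
    ax.set_title(title or f"RIP indices — {seq_id}")

    if gc_panel:
        axg = axes[1, 0]
        axg.bar(x, 100 * data["gc"], width=th.step * 0.9, align="edge", color="steelblue")
        axg.set_ylabel("GC content (%)")

    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
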