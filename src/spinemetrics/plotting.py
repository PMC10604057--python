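"""Optional figures: Bland-Altman plots and success-rate curves."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import BlandAltmanResult, SuccessCurve, bland_altman

__all__ = ["plot_bland_altman", "plot_success_curves"]


def plot_bland_altman(
    x: Sequence[float],
    y: Sequence[float],
    path: Union[str, Path],
    title: str = "",
    result: Optional[BlandAltmanResult] = None,
) -> BlandAltmanResult:
    """Scatter of differences vs means with the mean-difference line (solid
    red) and the +/- 1.96 SD limits of agreement (dashed blue); writes
    PNG/SVG by extension and returns the underlying result."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = result or bland_altman(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2.0, x - y, s=12, alpha=0.6, color="k")
    ax.axhline(res.mean_diff, color="red", lw=1.5)
    for limit in (res.loa_lower, res.loa_upper):
        ax.axhline(limit, color="blue", ls="--", lw=1.2)
    ax.set_xlabel("mean of the two measurements (deg)")
    ax.set_ylabel("difference (deg)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return res


def plot_success_curves(
    curves: Dict[str, SuccessCurve], path: Union[str, Path], title: str = ""
) -> None:
    """Per-parameter success rate vs error threshold, one line per parameter."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        ax.plot(curve.thresholds, curve.rates, marker=".", label=name)
    ax.axhline(0.8, color="gray", ls=":", lw=1.0)
    ax.set_xlabel("error threshold (deg)")
    ax.set_ylabel("success rate")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
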