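"""sROC and Deeks funnel plots (matplotlib, file output only)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .meta import SROC, DeeksResult, StudyRecord

__all__ = ["plot_sroc", "plot_funnel"]


def plot_sroc(
    sroc: SROC,
    studies: Sequence[StudyRecord],
    path: Union[str, Path],
) -> None:
    """Summary ROC curve with study points sized by sample size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if studies:
        cells = np.array([[s.tp, s.fp, s.fn, s.tn] for s in studies], float) + 0.5
        tp, fp, fn, tn = cells.T
        sizes = cells.sum(axis=1)
        ax.scatter(
            fp / (fp + tn),
            tp / (tp + fn),
            s=80.0 * sizes / sizes.max(),
            alpha=0.5,
            label="studies",
        )
    if not sroc.degenerate:
        ax.plot(sroc.curve[:, 0], sroc.curve[:, 1], "k-", label="sROC")
    ax.plot(*sroc.summary_point, "r*", markersize=14, label="summary point")
    ax.plot([0, 1], [0, 1], ":", color="grey")
    ax.set_xlabel("false-positive rate (1 - specificity)")
    ax.set_ylabel("sensitivity")
    title = "summary ROC"
    if sroc.auc is not None:
        title += f" (AUC = {sroc.auc:.3f})"
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_funnel(
    result: DeeksResult, studies: Sequence[StudyRecord], path: Union[str, Path]
) -> None:
    """Deeks funnel: ln DOR against 1/sqrt(ESS) with the fitted regression."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = np.array([[s.tp, s.fp, s.fn, s.tn] for s in studies], float)
    cells[(cells == 0).any(axis=1)] += 0.5
    tp, fp, fn, tn = cells.T
    ln_dor = np.log(tp * tn / (fp * fn))
    x = 1.0 / np.sqrt(result.ess)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ln_dor, x, alpha=0.6)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(result.intercept + result.slope * grid, grid, "k-")
    ax.invert_yaxis()
    ax.set_xlabel("ln diagnostic odds ratio")
    ax.set_ylabel("1 / sqrt(effective sample size)")
    ax.set_title(f"Deeks funnel (slope p = {result.p_value:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
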