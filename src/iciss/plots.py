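"""Basic ROC and decile-calibration figures.

Matplotlib is imported lazily so the core pipeline has no plotting
dependency; install the ``plots`` extra (or matplotlib) to use these.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .evaluate import decile_table


def plot_roc(predictions: Sequence[float], outcomes: Sequence[int], ax=None, label=None):
    """ROC curve of predicted mortality against observed death."""
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    if ax is None:
        _, ax = plt.subplots()
    fpr, tpr, _ = roc_curve(outcomes, predictions)
    ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if label:
        ax.legend()
    return ax


def plot_calibration(
    predictions: Sequence[float], outcomes: Sequence[int], ax=None, label=None
):
    """Decile calibration plot: observed vs mean predicted mortality."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    table = decile_table(predictions, outcomes)
    ax.plot(table["mean_predicted"], table["observed"], "o-", label=label)
    lim = max(table["mean_predicted"].max(), table["observed"].max()) * 1.05
    ax.plot([0, lim], [0, lim], ls="-", color="grey", lw=1)
    ax.set_xlabel("mean predicted mortality (decile)")
    ax.set_ylabel("observed mortality (decile)")
    if label:
        ax.legend()
    return ax
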