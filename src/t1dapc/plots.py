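"""Publication-style figures."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS


def duration_profile_plot(hr_tab: pd.DataFrame, path=None, bands=DEFAULT_BANDS,
                          title="HR of cancer by duration of diabetes"):
    """Point plot of HR (95% CI) against diabetes duration, log-scaled HR axis.

    Bands are plotted in band order regardless of input row order.
    """
    if hr_tab is None or len(hr_tab) == 0:
        raise ValueError("empty HR table")
    order = {lab: i for i, lab in enumerate(bands.labels)}
    tab = hr_tab[hr_tab["label"].isin(order)].copy()
    if len(tab) == 0:
        raise ValueError("HR table has no duration-band rows")
    tab["_i"] = tab["label"].map(order)
    tab = tab.sort_values("_i")
    x = np.arange(len(tab))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(x, tab["hr"],
                yerr=[tab["hr"] - tab["lo95"], tab["hi95"] - tab["hr"]],
                fmt="o", capsize=3, color="#00468b")
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_yscale("log")
    ax.set_xticks(x, tab["label"])
    ax.set_xlabel("duration of diabetes (years)")
    ax.set_ylabel("hazard ratio vs general population")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
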