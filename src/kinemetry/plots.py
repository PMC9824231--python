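"""Report figures: error box plots and RMS bar charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def error_boxplot(per_sample: pd.DataFrame, path: str | Path, by: str = "sensor") -> None:
    """Box plot of the per-sample absolute error grouped by sensor."""
    fig, ax = plt.subplots(figsize=(7, 4))
    groups = sorted(per_sample[by].unique())
    ax.boxplot(
        [per_sample.loc[per_sample[by] == g, "error_deg"] for g in groups],
        tick_labels=groups,
        showfliers=False,
    )
    ax.set_ylabel("absolute error (deg)")
    ax.set_title("Absolute error vs gold standard")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rms_barchart(per_movement: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of RMSAE per movement and sensor."""
    pivot = per_movement.pivot_table(index="movement", columns="sensor", values="rmsae")
    ax = pivot.plot.bar(figsize=(9, 4))
    ax.set_ylabel("RMS of absolute error (deg)")
    ax.set_title("Error dispersion per movement")
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
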