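"""Rendering of state-dependence results: per-ROI tables and bar summaries."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def render_report(battery: pd.DataFrame, out_dir: str | Path) -> None:
    """Write an HTML per-cell table and a weak/strong bar figure.

    The figure mirrors the standard trial-sorting display: per region, the
    mean evoked amplitude of the weak-power and strong-power trial bins,
    for the alpha band on TMS events.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    battery.to_html(out / "state_dependence.html", index=False, float_format="%.4f")

    sub = battery[(battery["band"] == "alpha") & (battery["event_type"] == "tms")]
    sub = sub.dropna(subset=["weak_mean", "strong_mean"])
    if len(sub) == 0:
        return
    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(sub)), 4))
    x = range(len(sub))
    w = 0.38
    ax.bar([i - w / 2 for i in x], sub["weak_mean"], width=w, label="weak alpha", color="#3b6fb6")
    ax.bar([i + w / 2 for i in x], sub["strong_mean"], width=w, label="strong alpha", color="#c0392b")
    for i, (_, row) in enumerate(sub.iterrows()):
        if row["p_perm_cat"] < 0.05:
            ymax = max(row["weak_mean"], row["strong_mean"])
            ax.text(i, ymax * 1.02, "*", ha="center", fontsize=14)
    ax.set_xticks(list(x))
    ax.set_xticklabels(sub["roi"], rotation=45, ha="right")
    ax.set_ylabel("evoked amplitude (mean single-trial beta)")
    ax.set_title("TMS-evoked response by pre-event alpha state")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "weak_strong_bars.png", dpi=120)
    plt.close(fig)
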