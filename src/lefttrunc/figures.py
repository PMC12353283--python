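"""Distribution figures: risks, risk differences and risk ratios across setups.

One three-panel figure per analysis family and stratum, observed versus
unobserved scope, points jittered per replicate (a strip plot over setups).
Figures are conveniences for inspection; every number they show comes from the
per-replicate estimates table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["render_figures"]

logger = logging.getLogger(__name__)

_PANELS = (
    ("risk_exposed", "Risk, exposed arm"),
    ("rd", "Risk difference"),
    ("rr", "Risk ratio"),
)
_SCOPE_STYLE = {"observed": ("#b2182b", "observed (entry at 20 weeks)"),
                "unobserved": ("#2166ac", "unobserved (conception cohort)")}


def render_figures(estimates: pd.DataFrame, outdir: str | Path,
                   family: str) -> list[Path]:
    """Write one PNG per stratum; returns the paths written."""
    outdir = Path(outdir)
    if estimates.empty:
        logger.warning("render_figures: empty estimates frame; nothing drawn")
        return []
    written: list[Path] = []
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for z, df_z in estimates.groupby("stratum"):
        fig, axes = plt.subplots(1, 3, figsize=(12, 4), constrained_layout=True)
        drew_any = False
        for ax, (col, title) in zip(axes, _PANELS):
            if col not in df_z.columns or df_z[col].dropna().empty:
                logger.warning("render_figures: %s missing for stratum %d; panel skipped",
                               col, z)
                ax.set_visible(False)
                continue
            for scope, (color, label) in _SCOPE_STYLE.items():
                sub = df_z[df_z["scope"] == scope]
                xs = sub["setup_id"].to_numpy(dtype=float)
                xs = xs + rng.uniform(-0.18, 0.18, len(xs))
                ax.scatter(xs, sub[col], s=6, alpha=0.35, color=color, label=label,
                           edgecolors="none")
            ax.set_xlabel("setup")
            ax.set_title(title)
            drew_any = True
        if not drew_any:
            plt.close(fig)
            continue
        handles, labels = axes[0].get_legend_handles_labels()
        if handles:
            fig.legend(handles[:2], labels[:2], loc="upper center", ncol=2,
                       frameon=False, bbox_to_anchor=(0.5, 1.08))
        fig.suptitle(f"{family}, placentation stratum Z={z}", y=1.12)
        path = outdir / f"fig_{family}_z{z}.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
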