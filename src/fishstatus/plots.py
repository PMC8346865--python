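"""Basic figures: Kobe endpoint plot and ratio histograms (matplotlib optional)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def kobe_plot(verdicts: pd.DataFrame, path) -> None:
    """Endpoint Kobe plane: one marker per ensemble member with SE crosses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.axvspan(0, 1, color="#f4d7d7", zorder=0)
    ax.axhspan(1, max(2.0, float(np.nanmax(verdicts["u"])) * 1.2), color="#f7efc9", zorder=0)
    for _, row in verdicts.dropna(subset=["b", "u"]).iterrows():
        ax.errorbar(row["b"], row["u"], xerr=row["b_se"], yerr=row["u_se"],
                    fmt="o", ms=4, capsize=2,
                    label=f"{row['method']}:{row['target_kind']}")
    ax.axvline(1.0, color="k", lw=0.8)
    ax.axhline(1.0, color="k", lw=0.8)
    ax.set_xlabel("B / B$_{MSY}$")
    ax.set_ylabel("U / U$_{MSY}$")
    ax.legend(fontsize=5, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ratio_histograms(status_tables: dict[str, pd.DataFrame], path, bin_width: float = 0.1) -> None:
    """Overlaid histograms of most-recent B and U ratios per target kind."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for kind, st in status_tables.items():
        for ax, col in zip(axes, ("b_last", "u_last")):
            v = st[col].dropna().to_numpy()
            bins = np.arange(0, max(v.max(), bin_width) + bin_width, bin_width)
            ax.hist(v, bins=bins, alpha=0.5, label=kind)
    for ax, lab in zip(axes, ("B / B$_{target}$", "U / U$_{MSY}$")):
        ax.axvline(1.0, color="k", lw=0.8)
        ax.set_xlabel(lab)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
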