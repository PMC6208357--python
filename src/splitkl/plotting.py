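"""Minimal plotting helpers for sweep tables (requires matplotlib)."""

from __future__ import annotations

import numpy as np

#: log-scale floor for KL values, below which estimates are pure noise
KL_FLOOR = 1e-4


def plot_sweep(df, out_path, x="dt", floor: float = KL_FLOOR, title=None):
    """Plot KL vs timestep (or gamma) per (splitting, mode), log y-axis.

    KL values are floored at ``floor`` on the plot only; the underlying
    table is never clamped.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    modes = sorted(df["mode"].unique())
    fig, axes = plt.subplots(1, len(modes), figsize=(5 * len(modes), 4),
                             squeeze=False, sharey=True)
    for ax, mode in zip(axes[0], modes):
        sub = df[df["mode"] == mode]
        for splitting, grp in sub.groupby("splitting"):
            grp = grp.sort_values(x)
            y = np.maximum(grp["kl"], floor)
            lo = np.maximum(grp["ci_low"], floor)
            hi = np.maximum(grp["ci_high"], floor)
            ax.plot(grp[x], y, marker="o", label=splitting)
            ax.fill_between(grp[x], lo, hi, alpha=0.2)
        ax.set_yscale("log")
        ax.set_xlabel(x)
        ax.set_title(mode)
        ax.legend()
    axes[0][0].set_ylabel(r"$D_{\mathrm{KL}}$ (nats)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
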