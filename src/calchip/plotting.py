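"""Small matplotlib helpers for profiles and retention curves."""
from __future__ import annotations

from .coverage import RetentionSummary
from .metaprofile import MetaProfile, RatioProfile


def plot_metaprofiles(profiles: dict[str, MetaProfile], path: str | None = None):
    """Overlay anchor-centred profiles (one line per label); save when a path is given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, p in profiles.items():
        ax.plot(p.offsets / 1000.0, p.values, label=label, lw=1)
    ax.set_xlabel("distance from CDEIII anchor (kb)")
    ax.set_ylabel("calibrated occupancy (per 1M reads)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ratio_profile(ratio: RatioProfile, path: str | None = None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(ratio.offsets / 1000.0, ratio.values, lw=1)
    ax.axhline(1.0, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("distance from CDEIII anchor (kb)")
    ax.set_ylabel(ratio.orientation)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_retention(summary: RetentionSummary, chromosome: str, path: str | None = None):
    """Percent-remaining along one chromosome with its median as a dotted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    values = summary.percent[chromosome]
    x = (np.arange(len(values)) + 0.5) * summary.bin_size / 1000.0
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(x, values, lw=0.8)
    ax.axhline(summary.medians[chromosome], color="k", ls=":", lw=1,
               label=f"median {summary.medians[chromosome]:.1f}%")
    ax.set_xlabel(f"{chromosome} position (kb)")
    ax.set_ylabel("cohesin remaining (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
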