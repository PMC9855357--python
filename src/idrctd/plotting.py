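"""Minimal PNG summaries of the main result objects (all optional)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_rg_distribution", "plot_fret_histogram", "plot_contact_map"]


def plot_rg_distribution(dist, path) -> None:
    """Histogram of per-frame Rg with the modal bin marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.stairs(dist.densities, dist.bin_edges, fill=True, alpha=0.6)
    ax.axvline(dist.mode, color="k", lw=1, ls="--", label=f"mode {dist.mode:.1f} A")
    ax.set_xlabel("radius of gyration (A)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fret_histogram(hist, results=None, path=None) -> None:
    """Proximity-ratio histogram with the fitted mixture overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.stairs(hist.density, hist.bin_edges, fill=True, alpha=0.5, label="data")
    if results is not None:
        x = np.linspace(0, 1, 400)
        mix = results.mixture
        total = np.zeros_like(x)
        for c in mix.components:
            z = (norm.cdf((1 - c.mean) / c.sigma) - norm.cdf((0 - c.mean) / c.sigma))
            comp = c.weight * norm.pdf(x, c.mean, c.sigma) / z
            total += comp
            ax.plot(x, comp, lw=0.8, color="grey")
        ax.plot(x, total, lw=1.5, color="k", label=f"{mix.n_components}-state fit")
    ax.set_xlabel("proximity ratio E")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_contact_map(cmap, path) -> None:
    """Residue-pair contact probability matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.6))
    extent = (
        cmap.residue_numbers[0], cmap.residue_numbers[-1],
        cmap.residue_numbers[0], cmap.residue_numbers[-1],
    )
    im = ax.imshow(cmap.matrix, origin="lower", vmin=0, vmax=1,
                   extent=extent, cmap="viridis")
    fig.colorbar(im, ax=ax, label="contact probability")
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
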