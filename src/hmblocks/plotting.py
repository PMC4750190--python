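"""Plots: boundary-aligned ChIP metaprofiles and per-motif positional
profiles. Matplotlib with the Agg backend; every function writes a file and
returns the axes for further styling."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .positional import PositionalProfile
from .signal import MetaProfile


def plot_metaprofile(prof: MetaProfile, mark: str, path: str | Path):
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(prof.offsets / 1000, prof.mean_signal, lw=1.2)
    ax.axvline(0, color="crimson", ls=":", lw=1)
    ax.set_xlabel("distance to block boundary (kb)\nnegative = outside")
    ax.set_ylabel(f"mean normalized {mark} signal")
    ax.set_title(f"{mark} metaprofile (n = {prof.n_regions} boundaries)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return ax


def plot_positional(prof: PositionalProfile, path: str | Path):
    fig, ax = plt.subplots(figsize=(6, 3))
    x = [i * prof.window for i in range(prof.n_windows)]
    ax.plot(x, prof.window_counts, drawstyle="steps-post", lw=1.2)
    ax.axvline(prof.edge_window * prof.window, color="crimson", ls=":", lw=1)
    ax.set_xlabel("offset in boundary region (b, outside → inside)")
    ax.set_ylabel("mean hits / region")
    ax.set_title(f"{prof.motif_id}: z = {prof.z:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return ax
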