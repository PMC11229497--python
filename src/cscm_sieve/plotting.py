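"""Manhattan-style plots for association results and coverage profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import GenomeBuild
from .coverage import DepthProfile

_COLORS = ("#3b4cc0", "#888888")


def _genome_x(build: GenomeBuild, chroms: pd.Series, pos: pd.Series) -> tuple[np.ndarray, dict]:
    offsets = {}
    total = 0
    for name, length in zip(build.chrom_names, build.chrom_lengths):
        offsets[name] = total
        total += length
    x = pos.to_numpy() + np.array([offsets[c] for c in chroms])
    return x, offsets


def manhattan_plot(
    assoc: pd.DataFrame, build: GenomeBuild, path: str | Path, threshold: float | None = None
) -> Path:
    """-log10 p per genome position, chromosomes alternately colored."""
    df = assoc[assoc["informative"]] if "informative" in assoc else assoc
    x, offsets = _genome_x(build, df["chrom"], df["pos"])
    fig, ax = plt.subplots(figsize=(9, 3))
    for i, chrom in enumerate(build.chrom_names):
        sel = (df["chrom"] == chrom).to_numpy()
        ax.scatter(x[sel], -np.log10(df["p_value"].to_numpy()[sel]), s=4,
                   color=_COLORS[i % 2], rasterized=True)
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def coverage_plot(profile: DepthProfile, build: GenomeBuild, path: str | Path) -> Path:
    """Per-window normalized depth ratio with the genome-wide reference line."""
    df = profile.windows
    if "ratio" not in df.columns:
        raise ValueError("normalize the profile before plotting")
    x, _ = _genome_x(build, df["chrom"], df["start"])
    fig, ax = plt.subplots(figsize=(9, 3))
    for i, chrom in enumerate(build.chrom_names):
        sel = (df["chrom"] == chrom).to_numpy()
        ax.scatter(x[sel], df["ratio"].to_numpy()[sel], s=4, color=_COLORS[i % 2],
                   rasterized=True)
    ax.axhline(1.0, color="red", lw=0.8)
    ax.set_ylim(0, 2.2)
    ax.set_xlabel("genome position")
    ax.set_ylabel("depth ratio")
    ax.set_title(f"{profile.sample} ({profile.window_size // 1000} kb windows)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
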