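"""Optional figures: OJIP curves, delta-W bands, relative-profile radar, heatmap.

Tables are the pipeline's contract; everything here is cosmetic and only
produced behind the CLI ``--plots`` flag.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import FluorescenceTransient


def render_all(out_dir, transients, mean_bands, config: PipelineConfig) -> dict[str, Path]:
    out = Path(out_dir)
    produced = {}
    produced["plot_ojip"] = _plot_ojip(out, transients)
    produced["plot_delta_w"] = _plot_delta_w(out, config)
    produced["plot_radar"] = _plot_radar(out, config)
    produced["plot_corr"] = _plot_corr(out)
    return produced


def _plot_ojip(out: Path, transients: list[FluorescenceTransient]) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for tr in transients:
        ax.semilogx(tr.times, tr.fluorescence, lw=0.6, alpha=0.6,
                    label=f"{tr.variety} {tr.treatment}" if tr.replicate == 1 else None)
    ax.set_xlabel("time (µs)")
    ax.set_ylabel("fluorescence (a.u.)")
    ax.legend(fontsize=6, ncol=2)
    path = out / "ojip_curves.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _plot_delta_w(out: Path, config: PipelineConfig) -> Path:
    df = pd.read_csv(out / "band_curves.csv")
    delta = df[df["delta_W"].notna()] if "delta_W" in df else df.iloc[0:0]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=False)
    for ax, phase in zip(axes, ("OK", "OJ", "OI")):
        sub = delta[delta["phase"] == phase]
        for (variety, treatment), grp in sub.groupby(["variety", "treatment"]):
            ax.semilogx(grp["time_us"], grp["delta_W"], label=f"{variety} {treatment}")
        ax.set_title(f"delta-W {phase}")
        ax.set_xlabel("time (µs)")
        ax.axhline(0, color="k", lw=0.5)
    axes[0].legend(fontsize=6)
    fig.tight_layout()
    path = out / "delta_w_bands.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _plot_radar(out: Path, config: PipelineConfig) -> Path:
    prof = pd.read_csv(out / "relative_profiles.csv")
    traits = sorted(prof["trait"].unique())
    angles = np.linspace(0, 2 * np.pi, len(traits), endpoint=False)
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"projection": "polar"})
    for (variety, treatment), grp in prof.groupby(["variety", "treatment"]):
        vals = grp.set_index("trait").loc[traits, "value"].to_numpy()
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], lw=1,
                label=f"{variety} {treatment}")
    ax.set_xticks(angles)
    ax.set_xticklabels(traits, fontsize=6)
    ax.legend(fontsize=6, loc="lower right")
    path = out / "relative_profile_radar.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _plot_corr(out: Path) -> Path:
    long = pd.read_csv(out / "correlations.csv")
    traits = sorted(set(long["trait_i"]) | set(long["trait_j"]))
    mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for row in long.itertuples(index=False):
        mat.loc[row.trait_i, row.trait_j] = row.r
        mat.loc[row.trait_j, row.trait_i] = row.r
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(traits)), traits, rotation=90, fontsize=6)
    ax.set_yticks(range(len(traits)), traits, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    path = out / "correlation_heatmap.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
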