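"""Figure writers: percent-support scatters and z-difference heatmaps."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def support_scatter(points: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Per-group scatter of enriched-side vs depleted-side percent PED support.

    Points below the diagonal agree with the transcript-level call: the
    enriched side carries proportionally more peptide evidence.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for group, sub in points.groupby("group"):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot([0, 100], [0, 100], color="grey", lw=0.8)
        ax.scatter(
            sub["pct_ped_enriched_side"], sub["pct_ped_depleted_side"], s=14, alpha=0.7
        )
        ax.set_xlabel("% PEDs, enriched side")
        ax.set_ylabel("% PEDs, depleted side")
        ax.set_xlim(0, 102)
        ax.set_ylim(0, 102)
        ax.set_title(str(group))
        fig.tight_layout()
        path = outdir / f"support_{group}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def z_heatmap(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Event x group heatmap of main-minus-alternative z differences."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.12 * len(matrix))))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z(main) - z(alt)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
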