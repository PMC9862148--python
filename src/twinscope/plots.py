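"""Figure helpers: per-ROI asymmetry bar charts and Q-Q plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .luminosity import QQCurve


def asymmetry_bars(records: list[dict], outdir: str | Path) -> list[Path]:
    """One grouped bar chart per phenotype: ROIs on x, one bar per subject."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phenotypes = sorted({r["phenotype"] for r in records})
    written = []
    for ph in phenotypes:
        sub = [r for r in records if r["phenotype"] == ph]
        rois = sorted({r["roi"] for r in sub})
        subjects = sorted({r["subject_id"] for r in sub})
        fig, ax = plt.subplots(figsize=(10, 4))
        width = 0.8 / len(subjects)
        for j, sid in enumerate(subjects):
            vals = []
            for roi in rois:
                match = [r["index"] for r in sub if r["roi"] == roi and r["subject_id"] == sid]
                vals.append(match[0] if match else 0.0)
            ax.bar([i + j * width for i in range(len(rois))], vals, width, label=sid)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xticks([i + 0.4 for i in range(len(rois))])
        ax.set_xticklabels(rois, rotation=45, ha="right", fontsize=8)
        ax.set_ylabel("asymmetry index (L-R)/((L+R)/2)")
        ax.set_title(f"Hemispheric asymmetry: {ph}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"asymmetry_{ph}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def qq_plot(curve: QQCurve, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 255], [0, 255], "k--", lw=0.8, label="identity")
    ax.plot(curve.qx, curve.qy, "o-", ms=2, lw=0.8)
    ax.set_xlabel(curve.labels[0])
    ax.set_ylabel(curve.labels[1])
    ax.set_title(f"divergence = {curve.divergence:.4f}", fontsize=9)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)
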