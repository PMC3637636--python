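"""Diagnostic plot writers (image plus TSV companion)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import write_table
from .rhm import RHMResult
from .robust_pca import OutlierDiagnostics

__all__ = ["diagnostic_plot", "rhm_plot", "manhattan_plot"]


def diagnostic_plot(diag: OutlierDiagnostics, out_prefix, subject_ids=None, meta=None):
    """Orthogonal-distance versus score-distance scatter with cutoff lines.

    Writes ``<prefix>.png`` and ``<prefix>.tsv`` (subject, SD, OD, label)
    and returns both paths.
    """
    out_prefix = Path(out_prefix)
    n = diag.score_distance.size
    if subject_ids is None:
        subject_ids = [f"subj_{i + 1:05d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "score_distance": diag.score_distance,
            "orth_distance": diag.orth_distance,
            "label": diag.labels,
        }
    )
    tsv = write_table(
        df,
        out_prefix.with_suffix(".tsv"),
        meta={"sd_cutoff": diag.sd_cutoff, "od_cutoff": diag.od_cutoff, **(meta or {})},
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {"regular": "C0", "A": "C1", "B": "C2", "C": "C3"}
    for lab in ("regular", "A", "B", "C"):
        m = diag.labels == lab
        if m.any():
            ax.scatter(diag.score_distance[m], diag.orth_distance[m], s=12, c=colors[lab], label=lab)
    ax.axvline(diag.sd_cutoff, ls="--", c="k", lw=1)
    ax.axhline(diag.od_cutoff, ls="--", c="k", lw=1)
    ax.set_xlabel("score distance")
    ax.set_ylabel("orthogonal distance")
    ax.legend(title="type", fontsize=8)
    png = out_prefix.with_suffix(".png")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return png, tsv


def rhm_plot(result: RHMResult, out_prefix, subject_ids=None, meta=None):
    """Index versus mean-vector-length scatter with the median+3*MAD cutoff line."""
    out_prefix = Path(out_prefix)
    n = result.mean_lengths.size
    if subject_ids is None:
        subject_ids = [f"subj_{i + 1:05d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "mean_length": result.mean_lengths,
            "flagged": result.flags.astype(int),
        }
    )
    tsv = write_table(df, out_prefix.with_suffix(".tsv"), meta={"cutoff": result.cutoff, **(meta or {})})
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(np.arange(n), result.mean_lengths, s=10, c=np.where(result.flags, "C3", "C0"))
    ax.axhline(result.cutoff, ls="--", c="k", lw=1)
    ax.set_xlabel("subject index")
    ax.set_ylabel("mean scaled length")
    png = out_prefix.with_suffix(".png")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return png, tsv


def manhattan_plot(p_values, out_path, sqrt_scale: bool = True):
    """Simple -log10(p) plot over SNP index, optionally square-root scaled."""
    p = np.asarray(p_values, dtype=float)
    y = -np.log10(np.clip(p, 1e-300, 1.0))
    if sqrt_scale:
        y = np.sqrt(y)
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.scatter(np.arange(p.size), y, s=6)
    ax.set_xlabel("SNP index")
    ax.set_ylabel("sqrt(-log10 p)" if sqrt_scale else "-log10 p")
    out_path = Path(out_path)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
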