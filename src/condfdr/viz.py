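"""Diagnostic figures: conditional Q-Q plots, TDR curves, Manhattan plots.

All plotted values are computed by the statistical modules and exported as
delimited text next to each image; figures are views of those tables, never
recomputations.  Q-Q series are restricted to nominal -log10(p) < 7.3
(p > 5e-8) to focus on the sub-genome-wide-significant range where
pleiotropic enrichment matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .conditional import DEFAULT_MIN_SUBSET, conditional_subset

QQ_MAX_NEGLOG10_P = 7.3  # p > 5e-8
DEFAULT_THRESHOLDS = (0.0, 1.0, 2.0, 3.0)


@dataclass
class QQSeries:
    """One conditional Q-Q curve: x = -log10 q, y = -log10 p, sorted by x."""

    threshold: float
    x: np.ndarray
    y: np.ndarray
    n_subset: int
    flagged: bool = False  # subset smaller than the stability floor


def conditional_qq(primary: pd.DataFrame, secondary: pd.DataFrame,
                   thresholds=DEFAULT_THRESHOLDS,
                   min_subset_size: int = DEFAULT_MIN_SUBSET) -> list[QQSeries]:
    """Conditional Q-Q series of the primary phenotype at each -log10 p2 cutoff.

    For every threshold t, takes the joined SNPs with -log10 p2 >= t, and for
    each distinct p1 plots y = -log10 p1 against x = -log10 q where q is the
    subset's empirical cdf at p1.  Under the global null each series lies on
    x = y in expectation; pleiotropic enrichment shows as leftward shifts at
    stricter thresholds.  Series with subsets below ``min_subset_size`` are
    flagged but still returned.
    """
    series = []
    for t in thresholds:
        subset = conditional_subset(primary, secondary, t)
        n = len(subset)
        if n == 0:
            series.append(QQSeries(threshold=float(t), x=np.empty(0),
                                   y=np.empty(0), n_subset=0, flagged=True))
            continue
        p = np.sort(subset["P"].to_numpy(dtype=float))
        uniq, counts = np.unique(p, return_counts=True)
        q = np.cumsum(counts) / n
        y = -np.log10(uniq)
        keep = y < QQ_MAX_NEGLOG10_P
        x = -np.log10(q[keep])
        y = y[keep]
        order = np.argsort(x, kind="mergesort")
        series.append(QQSeries(threshold=float(t), x=x[order], y=y[order],
                               n_subset=n, flagged=n < min_subset_size))
    return series


def tdr_curves(qq: list[QQSeries]) -> list[pd.DataFrame]:
    """Per-series conditional TDR = 1 - p/q, clipped to [0, 1], pointwise.

    Returns one DataFrame per series with columns ``neglog10_p`` and ``tdr``.
    """
    curves = []
    for s in qq:
        p = 10.0 ** (-s.y)
        q = 10.0 ** (-s.x)
        with np.errstate(divide="ignore", invalid="ignore"):
            tdr = np.clip(1.0 - p / q, 0.0, 1.0)
        curves.append(pd.DataFrame({
            "threshold": s.threshold, "neglog10_p": s.y, "tdr": tdr,
        }))
    return curves


def plot_qq(series: list[QQSeries], out_path, title: str = "Conditional Q-Q"):
    """Render Q-Q series to an image and export the plotted table as TSV."""
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(5, 5))
    lim = 0.0
    for s in series:
        label = f"-log10(p2) >= {s.threshold:g} (n={s.n_subset})"
        ax.plot(s.x, s.y, drawstyle="steps-post", label=label)
        if s.x.size:
            lim = max(lim, s.x.max(), s.y.max())
    ax.plot([0, lim], [0, lim], "k:", lw=1, label="null (x = y)")
    ax.set_xlabel(r"empirical $-\log_{10}(q)$")
    ax.set_ylabel(r"nominal $-\log_{10}(p)$")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    _export_qq_table(series, out_path.with_suffix(".tsv"))
    return out_path


def _export_qq_table(series: list[QQSeries], path) -> None:
    frames = [
        pd.DataFrame({"threshold": s.threshold, "neglog10_q": s.x,
                      "neglog10_p": s.y, "flagged": s.flagged})
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def plot_tdr(curves: list[pd.DataFrame], out_path, title: str = "Conditional TDR"):
    """Render TDR curves and export the plotted table."""
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        t = curve["threshold"].iloc[0] if len(curve) else float("nan")
        ax.plot(curve["neglog10_p"], curve["tdr"], label=f"-log10(p2) >= {t:g}")
    ax.set_xlabel(r"nominal $-\log_{10}(p)$")
    ax.set_ylabel("conditional TDR")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    pd.concat(curves, ignore_index=True).to_csv(
        out_path.with_suffix(".tsv"), sep="\t", index=False)
    return out_path


def manhattan(assignments: pd.DataFrame, out_path, fdr_column: str = "CONDFDR",
              fdr_threshold: float = 0.05, representatives=None,
              title: str | None = None):
    """Conditional/conjunction Manhattan plot of -log10 FDR by position.

    SNPs with FDR below the threshold (-log10 FDR > 1.3 at the default 0.05)
    get large markers; ``representatives`` (an iterable of SNP ids, e.g. the
    pruned locus representatives) are outlined.  The plotted table is
    exported alongside the image.
    """
    out_path = Path(out_path)
    df = assignments.copy()
    df["NEGLOG10_FDR"] = -np.log10(df[fdr_column].to_numpy(dtype=float))

    chroms = sorted(df["CHR"].unique(), key=_chrom_key)
    offsets = {}
    pos = 0
    for c in chroms:
        offsets[c] = pos
        pos += int(df.loc[df["CHR"] == c, "BP"].max()) + 1
    df["_X"] = df["BP"].astype(int) + df["CHR"].map(offsets)

    sig = df[fdr_column] < fdr_threshold
    fig, ax = plt.subplots(figsize=(9, 3.5))
    for idx, c in enumerate(chroms):
        mask = (df["CHR"] == c) & ~sig
        ax.scatter(df.loc[mask, "_X"], df.loc[mask, "NEGLOG10_FDR"], s=3,
                   color=["0.55", "0.75"][idx % 2], rasterized=True)
    ax.scatter(df.loc[sig, "_X"], df.loc[sig, "NEGLOG10_FDR"], s=22,
               color="crimson", zorder=3, label=f"FDR < {fdr_threshold:g}")
    if representatives is not None:
        reps = df["SNP"].isin(set(representatives))
        ax.scatter(df.loc[reps, "_X"], df.loc[reps, "NEGLOG10_FDR"], s=40,
                   facecolors="none", edgecolors="black", zorder=4,
                   label="locus representative")
    ax.axhline(-np.log10(fdr_threshold), color="k", ls="--", lw=0.8)
    ax.set_xticks([offsets[c] + df.loc[df["CHR"] == c, "BP"].max() / 2
                   for c in chroms])
    ax.set_xticklabels(chroms, fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}$ FDR")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    export_cols = ["SNP", "CHR", "BP", fdr_column, "NEGLOG10_FDR"]
    df[export_cols].to_csv(out_path.with_suffix(".tsv"), sep="\t", index=False)
    return out_path


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))
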