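"""Figure helpers. Every plot is drawn from an already-written table, so
results are reproducible from the TSVs alone; plotting is optional and the
pipeline runs headless without it."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .composition import UNBIASED_DINUCLEOTIDE_FREQ
from .evolution import ENC_STRONG_BIAS_CUTOFF


def _save(fig, path: Path) -> None:
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gc_histogram(per_record: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(per_record["gc"] * 100, bins=30, color="steelblue", edgecolor="white")
    ax.set_xlabel("GC content (%)")
    ax.set_ylabel("CDS count")
    _save(fig, path)


def plot_gc_boxplot(per_record: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    data = [per_record[c] * 100 for c in ("gc1", "gc2", "gc3", "gc")]
    ax.boxplot(data, tick_labels=["1st", "2nd", "3rd", "All"])
    ax.set_ylabel("GC content (%)")
    _save(fig, path)


def plot_dinucleotides(profiles: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    for dataset, sub in profiles.groupby("dataset"):
        sub = sub.sort_values("dinucleotide")
        ax.plot(sub["dinucleotide"], sub["freq"], marker="o", label=dataset)
    ax.axhline(UNBIASED_DINUCLEOTIDE_FREQ, ls="--", c="grey",
               label="unbiased (1/16)")
    ax.set_ylabel("frequency")
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    _save(fig, path)


def plot_enc(scatter: pd.DataFrame, curve: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(scatter["gc3"], scatter["enc"], s=4, alpha=0.4)
    ax.plot(curve["gc3"], curve["enc_expected"], c="black", lw=1,
            label="expected")
    ax.axhline(ENC_STRONG_BIAS_CUTOFF, ls="--", c="red", lw=0.8, label="ENC = 35")
    ax.set_xlabel("GC3")
    ax.set_ylabel("ENC")
    ax.legend(fontsize=8)
    _save(fig, path)


def plot_deviation_histogram(hist: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    width = hist["bin_right"] - hist["bin_left"]
    ax.bar(hist["bin_left"], hist["frequency"], width=width, align="edge",
           color="steelblue", edgecolor="white")
    ax.set_xlabel("(ENC_exp - ENC_obs) / ENC_exp")
    ax.set_ylabel("frequency")
    _save(fig, path)


def plot_pr2(points: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(points["x"], points["y"], s=4, alpha=0.4)
    ax.axhline(0.5, c="grey", lw=0.8)
    ax.axvline(0.5, c="grey", lw=0.8)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + U3)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    _save(fig, path)


def plot_neutrality(index_rows: pd.DataFrame, slope: float, intercept: float,
                    path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(index_rows["gc3"], index_rows["gc12"], s=4, alpha=0.4)
    xs = np.linspace(index_rows["gc3"].min(), index_rows["gc3"].max(), 50)
    ax.plot(xs, intercept + slope * xs, c="black", lw=1)
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    _save(fig, path)


def plot_pca_scatter(scores: pd.DataFrame, groups: pd.Series | None,
                     variance: np.ndarray, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    if groups is not None:
        for g in pd.unique(groups):
            sel = groups == g
            ax.scatter(scores.loc[sel, "PC1"], scores.loc[sel, "PC2"],
                       s=6, alpha=0.5, label=str(g))
        ax.legend(fontsize=8)
    else:
        ax.scatter(scores["PC1"], scores["PC2"], s=6, alpha=0.5)
    ax.set_xlabel(f"PC1 ({variance[0]:.2f}%)")
    ax.set_ylabel(f"PC2 ({variance[1]:.2f}%)")
    _save(fig, path)


def plot_expression(strata: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sub in strata.groupby("gc_group"):
        ax.scatter(sub["enc"], sub["log10_fpkm"], s=6, alpha=0.5, label=g)
    ax.set_xlabel("ENC")
    ax.set_ylabel("log10 FPKM")
    ax.legend(fontsize=8)
    _save(fig, path)
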