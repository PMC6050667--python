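"""Principal-component decomposition of RSCU and amino-acid matrices.

Three decompositions mirror the standard codon-usage workflow: genes in
RSCU space (59 informative codons), codons in gene space (the transpose,
grouped by ending base), and genes in amino-acid-proportion space (20
residues). All run on column-centered, unscaled data — RSCU values and
simplex proportions already share a common scale — with an optional
``scale`` switch for unit-variance columns.

Per-gene RSCU entries for synonymous families the gene never uses are
imputed as 1.0, the no-information value that preserves family mass;
imputing 0 would encode strong avoidance that short genes cannot support.
Alternatives (``zero``, ``drop-gene``) are available for sensitivity
analysis, and imputed cells are flagged.

Axis signs are fixed by forcing the largest-magnitude loading of each axis
positive, so scores are reproducible across row orders and library
versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .genetic_code import AMINO_ACIDS, INFORMATIVE_CODONS, dna_to_rna
from .io import CdsRecord
from .metrics import count_codons, protein_indices, rscu

RNA_INFORMATIVE_CODONS = tuple(dna_to_rna(c) for c in INFORMATIVE_CODONS)


@dataclass(frozen=True)
class PcaResult:
    """Scores, loadings and explained-variance percentages of one PCA.

    ``scores`` has one row per item (gene or codon), columns PC1..PCk;
    ``variance_explained`` is in percent, non-increasing;
    ``group_labels`` aligns with scores rows (GC interval for genes,
    ending base for codons) when a grouping applies.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    group_labels: pd.Series | None = None


def rscu_gene_matrix(
    records: list[CdsRecord], impute: str = "one"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene RSCU matrix (genes x 59 codons) with imputation flags.

    ``impute`` is one of ``one`` (default), ``zero``, ``drop-gene``.
    Returns (matrix, boolean flag frame marking imputed cells; empty for
    drop-gene).
    """
    if impute not in ("one", "zero", "drop-gene"):
        raise ValueError(f"unknown impute mode {impute!r}")
    fill = {"one": 1.0, "zero": 0.0, "drop-gene": np.nan}[impute]
    rows, flag_rows, ids = [], [], []
    for r in records:
        profile = rscu(count_codons(r))
        row = [profile.rscu.get(c, fill) for c in RNA_INFORMATIVE_CODONS]
        flags = [c in profile.absent for c in RNA_INFORMATIVE_CODONS]
        if impute == "drop-gene" and any(flags):
            continue
        rows.append(row)
        flag_rows.append(flags)
        ids.append(r.id)
    matrix = pd.DataFrame(rows, index=ids, columns=RNA_INFORMATIVE_CODONS)
    flags = pd.DataFrame(flag_rows, index=ids, columns=RNA_INFORMATIVE_CODONS)
    return matrix, flags


def aa_proportion_matrix(records: list[CdsRecord]) -> pd.DataFrame:
    """Per-gene amino-acid proportion matrix (genes x 20), rows on the simplex."""
    rows = {
        r.id: [protein_indices(r.protein).aa_proportion[aa] for aa in AMINO_ACIDS]
        for r in records
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(AMINO_ACIDS))


def _run_pca(
    matrix: pd.DataFrame, n_components: int | None = None, scale: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    Xc = X - X.mean(axis=0)
    total_var = float((Xc**2).sum())
    max_k = min(X.shape)
    k = max_k if n_components is None else min(n_components, max_k)
    cols = [f"PC{i + 1}" for i in range(k)]
    if total_var <= 1e-24:  # rank-0 after centering: no variation at all
        scores = pd.DataFrame(0.0, index=matrix.index, columns=cols)
        loadings = pd.DataFrame(0.0, index=matrix.columns, columns=cols)
        return scores, loadings, np.zeros(k)
    if scale:
        sd = Xc.std(axis=0, ddof=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=k, svd_solver="full")
    S = pca.fit_transform(Xc)
    L = pca.components_.T  # features x axes
    # Deterministic sign: largest-|loading| entry of each axis positive.
    for j in range(k):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
            S[:, j] = -S[:, j]
    scores = pd.DataFrame(S, index=matrix.index, columns=cols)
    loadings = pd.DataFrame(L, index=matrix.columns, columns=cols)
    return scores, loadings, pca.explained_variance_ratio_ * 100.0


def gc_group_labels(
    gc: pd.Series, breaks: tuple[float, float] | None = None
) -> pd.Series:
    """Three-way GC grouping by (lower, upper) breaks; quartiles by default."""
    if breaks is None:
        q1, q3 = np.nanpercentile(gc.to_numpy(float), [25, 75])
        breaks = (float(q1), float(q3))
    lo, hi = breaks
    vals = gc.to_numpy(float)
    labels = np.select([vals < lo, vals > hi], ["low_gc", "high_gc"], "mid_gc")
    return pd.Series(labels, index=gc.index, name="gc_group")


def pca_genes_rscu(
    matrix: pd.DataFrame,
    gc: pd.Series | None = None,
    gc_breaks: tuple[float, float] | None = None,
    n_components: int | None = None,
    scale: bool = False,
) -> PcaResult:
    """PCA of genes in RSCU space, with optional GC-interval group labels."""
    scores, loadings, var = _run_pca(matrix, n_components, scale)
    groups = None
    if gc is not None:
        groups = gc_group_labels(gc.reindex(matrix.index), gc_breaks)
    return PcaResult(scores, loadings, var, groups)


def pca_codons_rscu(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    scale: bool = False,
) -> PcaResult:
    """PCA of the 59 codons in gene space (genes x codons input, transposed).

    Codons are labelled by ending base; per-group dispersion (mean distance
    from the group centroid in the first two axes) is attached as
    ``scores.attrs['group_dispersion']``.
    """
    t = matrix.T
    scores, loadings, var = _run_pca(t, n_components, scale)
    groups = pd.Series(
        [c[-1].replace("T", "U") for c in t.index],
        index=t.index,
        name="ending_base",
    )
    axes = [c for c in scores.columns[:2]]
    disp = {}
    for g in "AUGC":
        pts = scores.loc[groups == g, axes].to_numpy()
        if pts.size == 0:
            continue
        centroid = pts.mean(axis=0)
        disp[g] = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
    scores.attrs["group_dispersion"] = disp
    return PcaResult(scores, loadings, var, groups)


def pca_amino_acids(
    matrix: pd.DataFrame, n_components: int = 20, scale: bool = False
) -> PcaResult:
    """PCA of genes in amino-acid-proportion space, 20 axes requested.

    Cumulative variance over the first six axes is attached as
    ``scores.attrs['cumulative_first6_pct']``.
    """
    scores, loadings, var = _run_pca(matrix, n_components, scale)
    scores.attrs["cumulative_first6_pct"] = float(var[:6].sum())
    return PcaResult(scores, loadings, var)
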