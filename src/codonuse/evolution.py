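"""Inference layer: ENC plot, PR2 bias, neutrality regression, correlations,
expression stratification, and focal gene-set comparison.

The ENC plot compares each gene's observed ENC against the curve expected
from its GC3 alone: genes on the curve are consistent with pure mutational
(compositional) bias, genes below it use fewer codons than their composition
predicts, the signature of selection. ENC = 35 is the conventional line
separating strong from weak codon usage bias.

Parity Rule 2: absent strand-specific mutation and selection, A ~ T(U) and
G ~ C at third codon positions. Each gene is placed at
x = G3/(G3+C3), y = A3/(A3+U3); quadrants are counted around (0.5, 0.5).

The neutrality plot regresses GC12 on GC3 across genes (ordinary least
squares). A slope of 1 means first/second positions track third-position
composition, i.e. mutation pressure alone; the slope scaled to percent is
reported as the mutation contribution and its complement as selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import AA_TO_CODONS, CODON_INDEX, FOLD_CLASSES
from .io import CdsRecord
from .metrics import count_codons, expected_enc_curve

ENC_STRONG_BIAS_CUTOFF = 35.0


def enc_plot_data(
    index_rows: pd.DataFrame, n_curve_points: int = 1000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter layer (gc3, enc, above/below-curve status) and expected curve.

    Requires >= 2 genes with defined ENC. The returned scatter carries a
    ``below_curve`` flag (observed < expected) and a ``strong_bias`` flag
    (ENC < 35).
    """
    rows = index_rows.dropna(subset=["enc"])
    if len(rows) == 0:
        raise ValueError("all ENC values undefined")
    if len(rows) < 2:
        raise ValueError("need at least 2 genes with defined ENC")
    scatter = rows[["id", "gc3", "enc", "enc_expected"]].copy()
    scatter["below_curve"] = scatter["enc"] < scatter["enc_expected"]
    scatter["strong_bias"] = scatter["enc"] < ENC_STRONG_BIAS_CUTOFF
    return scatter, expected_enc_curve(n_curve_points)


def deviation_histogram(
    deviations: np.ndarray | list[float], bin_width: float = 0.01
) -> pd.DataFrame:
    """Histogram of ENC deviation ratios with half-open bins aligned to zero.

    Returns (bin_left, bin_right, count, frequency); frequencies sum to 1.
    """
    d = np.asarray(deviations, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no finite deviations")
    lo = int(np.floor(d.min() / bin_width))
    hi = int(np.floor(d.max() / bin_width)) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": counts / counts.sum(),
        }
    )


def bootstrap_deviation_histogram(
    deviations: np.ndarray | list[float],
    bin_width: float = 0.01,
    n_replicates: int = 2500,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-resampling bootstrap confidence bands for the deviation histogram.

    Resamples genes with replacement ``n_replicates`` times and returns the
    2.5/97.5 percentile envelope of each bin's frequency alongside the
    observed histogram.
    """
    base = deviation_histogram(deviations, bin_width)
    d = np.asarray(deviations, dtype=float)
    d = d[np.isfinite(d)]
    rng = np.random.default_rng(seed)
    edges = np.append(base["bin_left"].to_numpy(), base["bin_right"].iloc[-1])
    freqs = np.empty((n_replicates, len(base)))
    for i in range(n_replicates):
        counts, _ = np.histogram(rng.choice(d, size=d.size), bins=edges)
        freqs[i] = counts / d.size
    base["freq_lo"] = np.percentile(freqs, 2.5, axis=0)
    base["freq_hi"] = np.percentile(freqs, 97.5, axis=0)
    return base


_FOURFOLD_CODONS = frozenset(
    c for aa in FOLD_CLASSES[4] for c in AA_TO_CODONS[aa]
)


def pr2_analysis(
    records: list[CdsRecord], fourfold_only: bool = False
) -> tuple[pd.DataFrame, dict[str, int]]:
    """PR2 bias coordinates per gene and quadrant tallies.

    Third-position base counts are taken over all sense codons by default;
    ``fourfold_only=True`` restricts to fourfold-degenerate families (the
    classical variant, where third-position changes are always synonymous).
    Quadrants around (0.5, 0.5): Q1 both > 0.5; Q2 y > 0.5, x < 0.5; Q3
    both < 0.5; Q4 y < 0.5, x > 0.5. Points exactly on either 0.5 line are
    'boundary'; zero-denominator points are 'undefined'. Neither enters the
    quadrant tallies.
    """
    if not records:
        raise ValueError("no records")
    rows = []
    tallies = {"Q1": 0, "Q2": 0, "Q3": 0, "Q4": 0, "boundary": 0, "undefined": 0}
    for r in records:
        counts = count_codons(r)
        b3 = {b: 0 for b in "ACGT"}
        for aa, codons in AA_TO_CODONS.items():
            for c in codons:
                if fourfold_only and c not in _FOURFOLD_CODONS:
                    continue
                b3[c[2]] += int(counts.counts[CODON_INDEX[c]])
        au = b3["A"] + b3["T"]
        gc = b3["G"] + b3["C"]
        x = b3["G"] / gc if gc > 0 else np.nan
        y = b3["A"] / au if au > 0 else np.nan
        if not (np.isfinite(x) and np.isfinite(y)):
            q = "undefined"
        elif x == 0.5 or y == 0.5:
            q = "boundary"
        elif x > 0.5 and y > 0.5:
            q = "Q1"
        elif x < 0.5 and y > 0.5:
            q = "Q2"
        elif x < 0.5 and y < 0.5:
            q = "Q3"
        else:
            q = "Q4"
        tallies[q] += 1
        rows.append(dict(id=r.id, x=x, y=y, quadrant=q))
    return pd.DataFrame(rows), tallies


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 with the mutation/selection decomposition."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    @property
    def mutation_pct(self) -> float:
        return 100.0 * self.slope

    @property
    def selection_pct(self) -> float:
        return 100.0 * (1.0 - self.slope)


def neutrality_fit(gc12: np.ndarray, gc3: np.ndarray) -> NeutralityFit:
    """Ordinary least squares of GC12 (response) on GC3 (predictor)."""
    gc12 = np.asarray(gc12, dtype=float)
    gc3 = np.asarray(gc3, dtype=float)
    ok = np.isfinite(gc12) & np.isfinite(gc3)
    gc12, gc3 = gc12[ok], gc3[ok]
    if gc12.size < 3:
        raise ValueError("need at least 3 genes")
    if np.var(gc3) == 0:
        raise ValueError("zero GC3 variance")
    fit = stats.linregress(gc3, gc12)
    return NeutralityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(gc12.size),
    )


DEFAULT_CORRELATION_PAIRS = (
    ("enc", "aa_pca1"),
    ("enc", "rscu_pca1"),
    ("enc", "length_aa"),
    ("enc", "gravy"),
    ("enc", "aromo"),
    ("rscu_pca1", "length_aa"),
    ("rscu_pca1", "gravy"),
    ("rscu_pca1", "aromo"),
    ("aa_pca1", "rscu_pca1"),
)


def correlation_suite(
    index_rows: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] | None = None,
) -> pd.DataFrame:
    """Pearson correlations with two-sided p-values for column pairs.

    The default pair list relates ENC and the RSCU primary axis to protein
    length, hydropathy, aromaticity and the amino-acid primary axis
    (skipping pairs whose columns are absent). Constant columns yield
    r = NaN with a flag.
    """
    if pairs is None:
        pairs = tuple(
            (a, b)
            for a, b in DEFAULT_CORRELATION_PAIRS
            if a in index_rows.columns and b in index_rows.columns
        )
    rows = []
    for a, b in pairs:
        sub = index_rows[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"pair ({a}, {b}) has fewer than 3 complete cases")
        xa, xb = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.var(xa) == 0 or np.var(xb) == 0:
            rows.append(dict(x=a, y=b, pearson_r=np.nan, p_value=np.nan,
                             n=n, constant_column=True))
            continue
        r, p = stats.pearsonr(xa, xb)
        rows.append(dict(x=a, y=b, pearson_r=float(r), p_value=float(p),
                         n=n, constant_column=False))
    return pd.DataFrame(rows)


def expression_stratification(
    index_rows: pd.DataFrame,
    fpkm_cutoff: float = 1.0,
    gc_breaks: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GC-stratified expression table for FPKM-above-cutoff genes.

    Genes with FPKM strictly above ``fpkm_cutoff`` are kept and assigned to
    three GC groups: below the lower break, between the breaks, above the
    upper break. Breaks default to the lower/upper quartiles of the whole
    dataset's per-gene GC content (computed before the FPKM filter). Returns
    (per-gene table with gc_group, per-group summary of mean ENC and GC).
    """
    if "fpkm" not in index_rows.columns:
        raise ValueError("index table has no fpkm column")
    if gc_breaks is None:
        q1, q3 = np.nanpercentile(index_rows["gc"].to_numpy(float), [25, 75])
        gc_breaks = (float(q1), float(q3))
    lo, hi = gc_breaks
    kept = index_rows[index_rows["fpkm"] > fpkm_cutoff].copy()
    if len(kept) == 0:
        raise ValueError("no rows above threshold")
    gc = kept["gc"].to_numpy(float)
    kept["gc_group"] = np.select(
        [gc < lo, gc > hi], ["low_gc", "high_gc"], default="mid_gc"
    )
    summary = (
        kept.groupby("gc_group")
        .agg(n=("id", "size"), mean_enc=("enc", "mean"), mean_gc=("gc", "mean"))
        .reset_index()
    )
    summary.attrs["gc_breaks"] = gc_breaks
    cols = ["id", "log10_fpkm", "enc", "gc", "gc_group"]
    return kept[[c for c in cols if c in kept.columns]], summary


@dataclass(frozen=True)
class GeneSetComparison:
    """Focal gene set vs dataset-average ENC and GC12/GC3 ratio."""

    table: pd.DataFrame
    mean_enc: float
    mean_gc12_gc3_ratio: float
    missing_ids: tuple[str, ...]

    @property
    def n_enc_below_average(self) -> int:
        return int(self.table["enc_below_average"].sum())

    @property
    def n_ratio_below_average(self) -> int:
        return int(self.table["ratio_below_average"].sum())


def gene_set_compare(
    index_rows: pd.DataFrame, gene_ids: list[str]
) -> GeneSetComparison:
    """Compare a focal gene set's ENC and GC12/GC3 ratios to dataset means.

    Flags use strict comparison against the dataset-wide mean ENC and mean
    GC12/GC3 ratio. Missing ids are reported, not fatal; an empty
    intersection is an error.
    """
    all_ratio = index_rows["gc12"] / index_rows["gc3"]
    mean_enc = float(index_rows["enc"].mean())
    mean_ratio = float(all_ratio.mean())
    present = index_rows[index_rows["id"].isin(gene_ids)].copy()
    missing = tuple(i for i in gene_ids if i not in set(index_rows["id"]))
    if len(present) == 0:
        raise ValueError("no focal gene ids found in the index table")
    present["gc12_gc3_ratio"] = present["gc12"] / present["gc3"]
    present["enc_below_average"] = present["enc"] < mean_enc
    present["ratio_below_average"] = present["gc12_gc3_ratio"] < mean_ratio
    table = present[
        ["id", "enc", "gc12_gc3_ratio", "enc_below_average", "ratio_below_average"]
    ].reset_index(drop=True)
    return GeneSetComparison(
        table=table,
        mean_enc=mean_enc,
        mean_gc12_gc3_ratio=mean_ratio,
        missing_ids=missing,
    )
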