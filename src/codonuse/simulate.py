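"""Synthetic CDS sets with known mutation/selection ground truth.

The generator emulates the mutation-selection view of codon usage at the
level the downstream analyses can see: composition, not evolutionary time.
Each gene draws a length (lognormal, truncated at 100 aa) and an FPKM
(lognormal); its amino-acid sequence is drawn independently of the codon
model (uniform by default), so amino-acid composition is null by
construction and any detected coupling with codon usage flags a bug. Within
each synonymous family, codon ``c`` is chosen with probability proportional
to

    base(c; m) * exp(s_g * 1[c ends in a selected base])

where ``m`` is the mutational GC bias (the weight of G/C-ending codons; at
m = 0.5 every family is uniform) and ``s_g`` is the gene's effective
selection log-weight, optionally coupled to its expression level through
the log-FPKM z-score. With ``mutation_all_positions=True``, codons are
instead drawn over all 61 sense codons with the compositional bias applied
at every position, the regime in which GC12 tracks GC3 and the neutrality
slope approaches 1.

Every simulated gene starts with ATG, ends with TAA, and passes the
sequence-validation filters by construction. The same seed reproduces
byte-identical output.

The module also packages a published genome-wide RSCU table for the buffalo
leech *Hirudinaria manillensis* (18,000 transcriptome CDSs), stored exactly
as printed — including its small rounding residues — as a classification
fixture with known preferred-codon structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import AA_TO_CODONS, AMINO_ACIDS, SENSE_CODONS, rna_to_dna
from .io import CdsRecord, make_cds_record
from .metrics import RscuProfile


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of the synthetic CDS generator.

    Parameters
    ----------
    n_genes : number of genes.
    median_length_aa, sigma_length : median (aa) and log-sd of the lognormal
        protein-length distribution, truncated at ``min_length_aa`` (300 aa
        median matches a typical transcriptome CDS pool of ~1 kb mean).
    gc_bias : mutational GC bias m in (0, 1) — the relative weight of
        G/C-ending codons in neutral synonymous choice. A (low, high) tuple
        draws a per-gene bias uniformly, giving the across-gene GC3 spread
        the regression analyses need.
    selection_strength : selection log-weight s >= 0 added to codons ending
        in ``selection_endings`` (RNA letters).
    selection_expression_coupling : scales s per gene by its log-FPKM
        z-score, s_g = max(0, s * (1 + coupling * z)); positive coupling
        gives highly expressed genes stronger codon selection.
    mutation_all_positions : apply the compositional bias at all three codon
        positions (codons drawn over all 61 sense codons) instead of only
        the third.
    fpkm_log_mean, fpkm_log_sigma : natural-log parameters of the lognormal
        FPKM distribution.
    aa_profile : optional 20-vector of amino-acid probabilities (alphabetical
        one-letter order); uniform if omitted.
    seed : mandatory integer seed; identical seeds give identical output.
    """

    seed: int
    n_genes: int = 2000
    median_length_aa: float = 300.0
    sigma_length: float = 0.45
    min_length_aa: int = 100
    gc_bias: float | tuple[float, float] = 0.5
    selection_strength: float = 0.0
    selection_endings: tuple[str, ...] = ("C", "G")
    selection_expression_coupling: float = 0.0
    mutation_all_positions: bool = False
    fpkm_log_mean: float = 1.0
    fpkm_log_sigma: float = 2.0
    aa_profile: tuple[float, ...] | None = None


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-gene realized ground truth plus an echo of the parameters."""

    params: SimulationParams
    per_gene: pd.DataFrame  # id, length_aa, fpkm, gc_bias, selection, gc3


_FAMILIES = [np.array(AA_TO_CODONS[aa]) for aa in AMINO_ACIDS]
_FAM_GC3 = [np.array([c[2] in "GC" for c in fam]) for fam in _FAMILIES]
_SENSE = np.array(SENSE_CODONS)
_SENSE_GC3 = np.array([c[2] in "GC" for c in SENSE_CODONS])


def _validate(params: SimulationParams) -> None:
    if params.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    m = params.gc_bias
    lo, hi = (m, m) if np.isscalar(m) else m
    if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0 and lo <= hi):
        raise ValueError(f"gc_bias must lie in (0, 1), got {m}")
    if params.selection_strength < 0:
        raise ValueError("selection_strength must be >= 0")
    bad = set(params.selection_endings) - set("AUGC")
    if bad:
        raise ValueError(f"selection_endings must be RNA bases, got {bad}")
    if params.median_length_aa < params.min_length_aa / 4:
        raise ValueError("length distribution incompatible with truncation")
    if params.aa_profile is not None:
        p = np.asarray(params.aa_profile, dtype=float)
        if p.shape != (20,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("aa_profile must be 20 non-negative values summing to 1")


def _draw_lengths(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    mu = np.log(params.median_length_aa)
    lengths = np.rint(
        rng.lognormal(mu, params.sigma_length, params.n_genes)
    ).astype(int)
    for _ in range(1000):
        short = lengths < params.min_length_aa
        if not short.any():
            return lengths
        lengths[short] = np.rint(
            rng.lognormal(mu, params.sigma_length, int(short.sum()))
        ).astype(int)
    raise ValueError("length truncation rejects nearly all draws")


def simulate_cds_set(
    params: SimulationParams,
) -> tuple[list[CdsRecord], pd.DataFrame, SyntheticTruth]:
    """Generate (CDS records, expression table, ground truth)."""
    _validate(params)
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    lengths = _draw_lengths(params, rng)
    fpkm = rng.lognormal(params.fpkm_log_mean, params.fpkm_log_sigma, n)
    z = (np.log(fpkm) - params.fpkm_log_mean) / params.fpkm_log_sigma
    s_gene = np.maximum(
        0.0,
        params.selection_strength
        * (1.0 + params.selection_expression_coupling * z),
    )
    if np.isscalar(params.gc_bias):
        m_gene = np.full(n, float(params.gc_bias))
    else:
        lo, hi = params.gc_bias
        m_gene = rng.uniform(lo, hi, n)
    aa_p = (
        np.full(20, 1 / 20)
        if params.aa_profile is None
        else np.asarray(params.aa_profile, dtype=float)
    )
    sel_third = np.array(
        [c[2] in {rna_to_dna(b) for b in params.selection_endings}
         for c in SENSE_CODONS]
    )
    fam_sel = [
        np.array([c[2] in {rna_to_dna(b) for b in params.selection_endings}
                  for c in fam])
        for fam in _FAMILIES
    ]

    records: list[CdsRecord] = []
    gc3_realized = np.empty(n)
    for g in range(n):
        L = int(lengths[g])
        m, s = float(m_gene[g]), float(s_gene[g])
        if params.mutation_all_positions:
            base = np.ones(len(_SENSE))
            for pos in range(3):
                in_gc = np.array([c[pos] in "GC" for c in SENSE_CODONS])
                base *= np.where(in_gc, m / 2.0, (1.0 - m) / 2.0)
            w = base * np.exp(s * sel_third)
            w /= w.sum()
            codon_idx = rng.choice(len(_SENSE), size=L, p=w)
            codons = _SENSE[codon_idx]
        else:
            aa_idx = rng.choice(20, size=L, p=aa_p)
            codons = np.empty(L, dtype="<U3")
            for ai in range(20):
                pos = np.flatnonzero(aa_idx == ai)
                if pos.size == 0:
                    continue
                fam = _FAMILIES[ai]
                w = np.where(_FAM_GC3[ai], m, 1.0 - m) * np.exp(s * fam_sel[ai])
                w /= w.sum()
                codons[pos] = fam[rng.choice(len(fam), size=pos.size, p=w)]
        seq = "ATG" + "".join(codons) + "TAA"
        records.append(make_cds_record(f"g{g:05d}", seq))
        # gc3 over sense codons, initial ATG included (its third base is G)
        gc3_realized[g] = (sum(c[2] in "GC" for c in codons) + 1) / (L + 1)

    expression = pd.DataFrame(
        {"id": [r.id for r in records], "fpkm": fpkm}
    )
    per_gene = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "length_aa": lengths,
            "fpkm": fpkm,
            "gc_bias": m_gene,
            "selection": s_gene,
            "gc3": gc3_realized,
        }
    )
    return records, expression, SyntheticTruth(params=params, per_gene=per_gene)


def write_simulation(
    records: list[CdsRecord],
    expression: pd.DataFrame,
    truth: SyntheticTruth,
    outdir: str | Path,
    line_width: int = 60,
) -> None:
    """Write cds.fasta, expression.tsv and truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "cds.fasta", "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), line_width):
                fh.write(r.sequence[i : i + line_width] + "\n")
    expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    payload = {
        "params": asdict(truth.params),
        "per_gene": truth.per_gene.to_dict(orient="records"),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=float)


# Published genome-wide RSCU values for the buffalo leech *Hirudinaria
# manillensis* (18,000 transcriptome CDSs), stored exactly as printed.
# Family sums carry small rounding residues (e.g. Leu sums to 6.001).
_REFERENCE_RSCU = """\
amino_acid,codon,rscu
A,GCU,1.06
A,GCG,0.438
A,GCC,1.39
A,GCA,1.113
R,AGA,1.025
R,AGG,0.975
R,CGA,1.379
R,CGC,0.944
R,CGG,0.702
R,CGU,0.975
N,AAC,1.087
N,AAU,0.913
D,GAU,0.966
D,GAC,1.034
C,UGU,0.81
C,UGC,1.19
Q,CAA,0.962
Q,CAG,1.038
E,GAG,0.837
E,GAA,1.163
G,GGU,0.972
G,GGG,0.536
G,GGC,0.948
G,GGA,1.544
H,CAC,1.111
H,CAU,0.889
I,AUU,1.074
I,AUA,0.69
I,AUC,1.236
L,CUA,0.365
L,CUC,1.335
L,CUG,1.334
L,CUU,0.967
L,UUA,0.546
L,UUG,1.454
K,AAA,0.981
K,AAG,1.019
M,AUG,1
F,UUU,0.915
F,UUC,1.085
P,CCA,1.16
P,CCC,0.883
P,CCU,1.134
P,CCG,0.823
S,UCG,0.907
S,UCU,1.062
S,AGC,1.061
S,AGU,0.939
S,UCA,0.957
S,UCC,1.074
T,ACC,1.134
T,ACA,0.938
T,ACG,0.895
T,ACU,1.032
W,UGG,1
Y,UAC,1.15
Y,UAU,0.85
V,GUU,1.12
V,GUG,1.029
V,GUC,1.409
V,GUA,0.442
"""


def reference_rscu_table() -> pd.DataFrame:
    """The packaged leech reference RSCU table: 61 sense codons, as printed."""
    import io as _io

    return pd.read_csv(_io.StringIO(_REFERENCE_RSCU))


def reference_rscu_classification() -> dict:
    """Classify the reference table; returns counts and codon sets.

    The result carries the preferred-codon count, the ending-base tally of
    the preferred set, and the highly-preferred / avoided sets.
    """
    table = reference_rscu_table()
    profile = RscuProfile.from_values(dict(zip(table["codon"], table["rscu"])))
    return {
        "preferred_count": len(profile.preferred),
        "ending_base_tally": profile.ending_base_tally,
        "preferred": sorted(profile.preferred),
        "highly_preferred": sorted(profile.highly_preferred),
        "avoided": sorted(profile.avoided),
    }
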