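"""Per-gene codon-usage statistics: codon counts, RSCU, ENC, protein indices.

RSCU (relative synonymous codon usage) for codon ``c`` in a synonymous
family of size ``n`` with family total ``m`` is ``count_c / (m / n)``: 1
means the codon is used exactly as often as expected under uniform
synonymous choice. Codons are classified preferred (RSCU > 1), highly
preferred (> 1.25) and avoided (< 0.75), all strict inequalities.

ENC (effective number of codons) is Wright's statistic in [20, 61]. For an
amino acid with ``n`` synonyms, family total ``m >= 2`` and within-family
proportions ``p_i``, the homozygosity estimate is

    F = (m * sum(p_i^2) - 1) / (m - 1)

and with F̄_k the mean F over observed amino acids of degeneracy class k,

    ENC = 2 + 9/F̄_2 + 1/F̄_3 + 5/F̄_4 + 3/F̄_6.

If the single three-fold family (Ile) is unobserved, F̄_3 is estimated as
(F̄_2 + F̄_4)/2 (Wright's fallback); any other missing class, or a
non-positive F̄, leaves ENC undefined with a machine-readable reason.
Estimates above 61 (a finite-sample artefact of near-uniform usage) are
clamped to 61 and flagged.

The expected-ENC curve gives the ENC predicted from third-position GC
content ``s`` alone under pure compositional (mutational) bias:

    ENC_exp = 2 + s + 29 / (s^2 + (1 - s)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .genetic_code import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    CODON_INDEX,
    CODONS,
    FOLD_CLASSES,
    INFORMATIVE_CODONS,
    STOP_CODONS,
    dna_to_rna,
    encode_codons,
    rna_to_dna,
)
from .io import CdsRecord

AROMATIC_RESIDUES = frozenset("FYW")

_STOP_IDX = np.array([CODON_INDEX[c] for c in STOP_CODONS])
_SENSE_MASK = np.ones(64, dtype=bool)
_SENSE_MASK[_STOP_IDX] = False


@dataclass(frozen=True)
class CodonCountTable:
    """64-slot codon counts for one record or a pooled set.

    ``counts`` is indexed by the lexicographic DNA codon order of
    :data:`codonuse.genetic_code.CODONS`. Sense counts exclude terminal
    stops, which are tallied separately in ``n_terminal_stops``.
    """

    counts: np.ndarray
    n_terminal_stops: int = 0

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (64,):
            raise ValueError("counts must have shape (64,)")
        if (counts < 0).any():
            raise ValueError("negative codon count")
        object.__setattr__(self, "counts", counts)

    @property
    def n_codons(self) -> int:
        """Total sense codons."""
        return int(self.counts[_SENSE_MASK].sum())

    @property
    def stop_counts(self) -> int:
        """Internal stop-codon count (0 for validated records)."""
        return int(self.counts[_STOP_IDX].sum())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(
            self.counts + other.counts,
            self.n_terminal_stops + other.n_terminal_stops,
        )

    def family_counts(self, aa: str) -> dict[str, int]:
        return {c: int(self.counts[CODON_INDEX[c]]) for c in AA_TO_CODONS[aa]}


def count_codons(record: CdsRecord) -> CodonCountTable:
    """Frame-0 non-overlapping codon counts; terminal stop excluded."""
    idx = encode_codons(record.sense_sequence)
    return CodonCountTable(
        np.bincount(idx, minlength=64),
        n_terminal_stops=int(record.has_terminal_stop),
    )


def pool_counts(tables: list[CodonCountTable]) -> CodonCountTable:
    out = CodonCountTable(np.zeros(64, dtype=np.int64))
    for t in tables:
        out = out + t
    return out


@dataclass(frozen=True)
class RscuProfile:
    """RSCU values over the 59 informative codons plus classification sets.

    ``rscu`` is keyed by RNA codon. Codons of unobserved families are absent
    from ``rscu`` and listed in ``absent``. The ending-base tally counts the
    third bases of the preferred (RSCU > 1) set.
    """

    rscu: dict[str, float]
    absent: frozenset[str] = frozenset()

    @property
    def preferred(self) -> frozenset[str]:
        return frozenset(c for c, v in self.rscu.items() if v > 1.0)

    @property
    def highly_preferred(self) -> frozenset[str]:
        return frozenset(c for c, v in self.rscu.items() if v > 1.25)

    @property
    def avoided(self) -> frozenset[str]:
        return frozenset(c for c, v in self.rscu.items() if v < 0.75)

    @property
    def ending_base_tally(self) -> dict[str, int]:
        tally = {b: 0 for b in "AUGC"}
        for c in self.preferred:
            tally[c[-1]] += 1
        return tally

    @classmethod
    def from_values(cls, values: dict[str, float]) -> "RscuProfile":
        """Build a profile from any codon->RSCU mapping (RNA or DNA codons).

        Only the 59 informative codons are kept, so singleton codons (AUG,
        UGG, fixed at RSCU 1) never enter the classification sets.
        """
        informative_rna = {dna_to_rna(c) for c in INFORMATIVE_CODONS}
        rscu = {
            dna_to_rna(c): float(v)
            for c, v in values.items()
            if dna_to_rna(c) in informative_rna
        }
        return cls(rscu=rscu, absent=frozenset(informative_rna - set(rscu)))


def rscu(counts: CodonCountTable) -> RscuProfile:
    """RSCU of a codon count table (single record or pooled set)."""
    if counts.n_codons == 0:
        raise ValueError("all-zero codon count table")
    values: dict[str, float] = {}
    absent: set[str] = set()
    for aa in AMINO_ACIDS:
        fam = AA_TO_CODONS[aa]
        n = len(fam)
        if n == 1:
            continue
        fam_counts = np.array([counts.counts[CODON_INDEX[c]] for c in fam])
        total = fam_counts.sum()
        if total == 0:
            absent.update(dna_to_rna(c) for c in fam)
            continue
        for c, k in zip(fam, fam_counts):
            values[dna_to_rna(c)] = float(k * n / total)
    return RscuProfile(rscu=values, absent=frozenset(absent))


def pooled_rscu_table(records: list[CdsRecord]) -> pd.DataFrame:
    """Dataset-level RSCU: RSCU of the summed codon counts, with classes.

    Returns a DataFrame (amino_acid, codon, rscu, class) over the 59
    informative codons, class in {preferred, highly_preferred, avoided, -}.
    """
    profile = rscu(pool_counts([count_codons(r) for r in records]))
    rows = []
    for c in INFORMATIVE_CODONS:
        rc = dna_to_rna(c)
        v = profile.rscu.get(rc)
        if v is None:
            cls = "absent"
        elif v > 1.25:
            cls = "highly_preferred"
        elif v > 1.0:
            cls = "preferred"
        elif v < 0.75:
            cls = "avoided"
        else:
            cls = "-"
        rows.append(dict(amino_acid=_AA_OF_RNA[rc], codon=rc, rscu=v, cls=cls))
    return pd.DataFrame(rows).rename(columns={"cls": "class"})


_AA_OF_RNA = {dna_to_rna(c): aa for aa in AMINO_ACIDS for c in AA_TO_CODONS[aa]}


@dataclass(frozen=True)
class EncResult:
    """Wright's ENC with its per-class mean homozygosities.

    ``enc`` is NaN when undefined; ``reason`` then says why. ``clamped``
    flags estimates capped at 61.
    """

    enc: float
    f_bar: dict[int, float] = field(default_factory=dict)
    clamped: bool = False
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.enc)


def enc(counts: CodonCountTable) -> EncResult:
    """Wright's effective number of codons for one count table."""
    if counts.n_codons == 0:
        raise ValueError("all-zero codon count table")
    f_values: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for k, aas in FOLD_CLASSES.items():
        for aa in aas:
            fam = np.array(
                [counts.counts[CODON_INDEX[c]] for c in AA_TO_CODONS[aa]],
                dtype=float,
            )
            m = fam.sum()
            if m < 2:  # F undefined at m<=1
                continue
            p = fam / m
            f = (m * float(np.dot(p, p)) - 1.0) / (m - 1.0)
            f_values[k].append(f)
    f_bar: dict[int, float] = {
        k: float(np.mean(v)) for k, v in f_values.items() if v
    }
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    missing = [k for k in (2, 3, 4, 6) if k not in f_bar]
    if missing:
        return EncResult(np.nan, f_bar, reason="insufficient_families")
    if any(f_bar[k] <= 0 for k in (2, 3, 4, 6)):
        return EncResult(np.nan, f_bar, reason="nonpositive_homozygosity")
    value = 2.0 + 9.0 / f_bar[2] + 1.0 / f_bar[3] + 5.0 / f_bar[4] + 3.0 / f_bar[6]
    if value > 61.0:
        return EncResult(61.0, f_bar, clamped=True)
    return EncResult(float(value), f_bar)


def expected_enc(gc3: float) -> float:
    """Expected ENC from third-position GC content under pure mutational bias."""
    if not 0.0 < gc3 <= 1.0:
        raise ValueError(f"gc3 must be in (0, 1], got {gc3}")
    s = float(gc3)
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def expected_enc_curve(n_points: int = 1000) -> pd.DataFrame:
    """The standard curve sampled on the strictly increasing grid
    0.001, 0.002, ..., 1.000 (``n_points`` points)."""
    s = np.arange(1, n_points + 1) / n_points
    return pd.DataFrame(
        {"gc3": s, "enc_expected": [expected_enc(x) for x in s]}
    )


def enc_deviation(enc_obs: float, enc_exp: float) -> float:
    """(ENC_exp - ENC_obs) / ENC_exp; negative when observed exceeds expected."""
    if not enc_exp > 0:
        raise ValueError("expected ENC must be positive")
    return (enc_exp - enc_obs) / enc_exp


@dataclass(frozen=True)
class ProteinIndices:
    """Length, GRAVY, aromaticity and amino-acid proportions of one protein."""

    length_aa: int
    gravy: float
    aromo: float
    aa_proportion: dict[str, float]


def protein_indices(protein: str) -> ProteinIndices:
    """Kyte-Doolittle GRAVY, aromatic fraction (F+Y+W) and composition.

    Raises on non-canonical residues, naming the first offending position.
    """
    if not protein:
        raise ValueError("empty protein")
    for i, aa in enumerate(protein):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-canonical residue {aa!r} at position {i}")
    n = len(protein)
    gravy = sum(KYTE_DOOLITTLE[aa] for aa in protein) / n
    aromo = sum(protein.count(aa) for aa in AROMATIC_RESIDUES) / n
    props = {aa: protein.count(aa) / n for aa in AMINO_ACIDS}
    return ProteinIndices(
        length_aa=n, gravy=float(gravy), aromo=float(aromo), aa_proportion=props
    )


def gc3_of_counts(counts: CodonCountTable, exclude_singletons: bool = False) -> float:
    """Third-position GC proportion from a codon count table.

    ``exclude_singletons=True`` gives the gc3s variant that drops the Met and
    Trp codons whose third base carries no synonymous information.
    """
    total = 0
    gc = 0
    for i, c in enumerate(CODONS):
        if not _SENSE_MASK[i]:
            continue
        if exclude_singletons and c in ("ATG", "TGG"):
            continue
        k = int(counts.counts[i])
        total += k
        if c[2] in "GC":
            gc += k
    if total == 0:
        raise ValueError("no sense codons")
    return gc / total


def gene_index_table(
    records: list[CdsRecord],
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row of scalar indices per gene: the per-gene analysis table.

    Columns: id, n_codons, enc, enc_clamped, gc, gc1, gc2, gc3, gc3s, gc12,
    enc_expected, deviation, length_aa, gravy, aromo, pr2_x, pr2_y, and
    (when an expression table is supplied) fpkm / log10_fpkm.
    """
    from .composition import composition_summary  # local to avoid cycle

    rows = []
    for r in records:
        counts = count_codons(r)
        s = composition_summary(r)
        e = enc(counts)
        if e.defined and 0.0 < s.gc3 <= 1.0:
            exp = expected_enc(s.gc3)
            dev = enc_deviation(e.enc, exp)
        else:
            exp = np.nan
            dev = np.nan
        pi = protein_indices(r.protein)
        b3 = _third_base_counts(counts)
        pr2_x = b3["G"] / (b3["G"] + b3["C"]) if b3["G"] + b3["C"] > 0 else np.nan
        pr2_y = b3["A"] / (b3["A"] + b3["T"]) if b3["A"] + b3["T"] > 0 else np.nan
        rows.append(
            dict(
                id=r.id,
                n_codons=counts.n_codons,
                enc=e.enc,
                enc_clamped=e.clamped,
                gc=s.gc,
                gc1=s.gc1,
                gc2=s.gc2,
                gc3=s.gc3,
                gc3s=gc3_of_counts(counts, exclude_singletons=True),
                gc12=s.gc12,
                enc_expected=exp,
                deviation=dev,
                length_aa=pi.length_aa,
                gravy=pi.gravy,
                aromo=pi.aromo,
                pr2_x=pr2_x,
                pr2_y=pr2_y,
            )
        )
    df = pd.DataFrame(rows)
    if expression is not None:
        expr = expression[["id", "fpkm"]].copy()
        if "log10_fpkm" in expression.columns:
            expr["log10_fpkm"] = expression["log10_fpkm"]
        else:
            with np.errstate(divide="ignore"):
                expr["log10_fpkm"] = np.where(
                    expr["fpkm"] > 0, np.log10(expr["fpkm"]), np.nan
                )
        df = df.merge(expr, on="id", how="left")
    return df


def _third_base_counts(counts: CodonCountTable) -> dict[str, int]:
    out = {b: 0 for b in "ACGT"}
    for i, c in enumerate(CODONS):
        if _SENSE_MASK[i]:
            out[c[2]] += int(counts.counts[i])
    return out
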