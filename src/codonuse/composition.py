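"""Nucleotide composition, positional GC content, and dinucleotide analysis.

GC1/GC2/GC3 are the G+C proportions at the three codon positions over sense
codons (terminal stop excluded); GC12 is the arithmetic mean of GC1 and GC2.
GC3 includes the third positions of every sense codon, Met and Trp included;
a ``gc3s`` variant excluding the two singleton families is available in
:mod:`codonuse.metrics` for cross-checks.

The dinucleotide analysis builds four datasets per the positional framing of
codon pairs: the two within-codon pairs (positions 1-2 and 2-3), the
codon-bridging pair (position 3 of one codon with position 1 of the next,
within a record), and all overlapping dinucleotides of the sense sequence.
An initial ATG codon and the terminal stop are excluded from all four
datasets, since start and stop usage is constrained by signals other than
synonymous choice. Each dataset's observed/expected ratio uses the marginal
base frequencies of the positions that dataset actually pairs, so the ratio
is a pure association measure; 1/16 = 0.0625 is the unbiased frequency
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import DNA_BASES, dna_to_rna, encode_bases
from .io import CdsRecord

DINUCLEOTIDE_DATASETS = ("all", "1st&2nd", "2nd&3rd", "3rd&1st")

#: Unbiased dinucleotide frequency, 1/16.
UNBIASED_DINUCLEOTIDE_FREQ = 0.0625


@dataclass(frozen=True)
class CompositionSummary:
    """Base proportions and positional GC content of one record or a pool."""

    p_a: float
    p_c: float
    p_g: float
    p_u: float
    gc: float
    gc1: float
    gc2: float
    gc3: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


def _base_counts(record: CdsRecord) -> tuple[np.ndarray, np.ndarray]:
    """(overall base counts [4], positional base counts [3,4]) over sense codons."""
    b = encode_bases(record.sense_sequence).reshape(-1, 3)
    pos = np.stack([np.bincount(b[:, j], minlength=4) for j in range(3)])
    return pos.sum(axis=0), pos


def _summary_from_counts(total: np.ndarray, pos: np.ndarray) -> CompositionSummary:
    n = total.sum()
    p = total / n
    gc_pos = (pos[:, 1] + pos[:, 2]) / pos.sum(axis=1)
    return CompositionSummary(
        p_a=float(p[0]),
        p_c=float(p[1]),
        p_g=float(p[2]),
        p_u=float(p[3]),
        gc=float(p[1] + p[2]),
        gc1=float(gc_pos[0]),
        gc2=float(gc_pos[1]),
        gc3=float(gc_pos[2]),
    )


def composition_summary(record: CdsRecord) -> CompositionSummary:
    """Composition of a single record, over sense codons only."""
    return _summary_from_counts(*_base_counts(record))


def nucleotide_content(
    records: list[CdsRecord], pooled: bool = True
) -> CompositionSummary | pd.DataFrame:
    """Base composition of a CDS set.

    Pooled mode concatenates counts over all records before normalizing
    (invariant to record order and to splitting records at codon
    boundaries). Per-record mode returns a DataFrame with one row per id.
    """
    if not records:
        raise ValueError("no records")
    if pooled:
        total = np.zeros(4, dtype=np.int64)
        pos = np.zeros((3, 4), dtype=np.int64)
        for r in records:
            t, p = _base_counts(r)
            total += t
            pos += p
        return _summary_from_counts(total, pos)
    rows = []
    for r in records:
        s = composition_summary(r)
        rows.append(
            dict(
                id=r.id,
                p_a=s.p_a, p_c=s.p_c, p_g=s.p_g, p_u=s.p_u,
                gc=s.gc, gc1=s.gc1, gc2=s.gc2, gc3=s.gc3, gc12=s.gc12,
            )
        )
    return pd.DataFrame(rows)


GC_HISTOGRAM_EDGES = (0.30, 0.42, 0.50, 0.60)


def gc_histogram(
    gc_values: np.ndarray | list[float],
    edges: tuple[float, ...] = GC_HISTOGRAM_EDGES,
) -> np.ndarray:
    """Count genes per GC interval with half-open [lo, hi) bins.

    The default edges give five bins: <30%, 30-42%, 42-50%, 50-60%, >=60%.
    """
    gc = np.asarray(gc_values, dtype=float)
    bins = np.concatenate(([-np.inf], edges, [np.inf]))
    counts, _ = np.histogram(gc, bins=bins)
    return counts


def _dinucleotide_pairs(b: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """First/second base index arrays for each dataset, from codon array (n,3)."""
    flat = b.reshape(-1)
    return {
        "all": (flat[:-1], flat[1:]),
        "1st&2nd": (b[:, 0], b[:, 1]),
        "2nd&3rd": (b[:, 1], b[:, 2]),
        "3rd&1st": (b[:-1, 2], b[1:, 0]),
    }


def dinucleotide_profiles(
    records: list[CdsRecord],
    global_marginals: bool = False,
    average_records: bool = False,
) -> pd.DataFrame:
    """Observed dinucleotide frequencies and observed/expected ratios.

    Returns a long-format DataFrame (dataset, dinucleotide, freq, ratio),
    64 rows. Ratios divide each observed frequency by the product of the
    marginal base frequencies of the two positions the dataset pairs;
    ``global_marginals=True`` uses whole-sequence base content for every
    dataset instead. ``average_records=True`` averages per-record frequency
    matrices rather than pooling counts.
    """
    if not records:
        raise ValueError("no records")
    joint: dict[str, np.ndarray] = {
        d: np.zeros((4, 4), dtype=float) for d in DINUCLEOTIDE_DATASETS
    }
    global_counts = np.zeros(4, dtype=float)
    n_used = 0
    for rec in records:
        seq = rec.sense_sequence
        if seq[:3] == "ATG":
            seq = seq[3:]
        if len(seq) < 9:  # fewer than 3 codons after exclusions
            warnings.warn(
                f"record {rec.id!r} has <3 codons after start/stop exclusion; skipped",
                stacklevel=2,
            )
            continue
        n_used += 1
        b = encode_bases(seq).reshape(-1, 3)
        rec_joint = {}
        for d, (first, second) in _dinucleotide_pairs(b).items():
            m = np.zeros((4, 4), dtype=float)
            np.add.at(m, (first, second), 1.0)
            rec_joint[d] = m
        if average_records:
            for d, m in rec_joint.items():
                joint[d] += m / m.sum()
            global_counts += np.bincount(b.reshape(-1), minlength=4) / b.size
        else:
            for d, m in rec_joint.items():
                joint[d] += m
            global_counts += np.bincount(b.reshape(-1), minlength=4)
    if n_used == 0:
        raise ValueError("no usable records for dinucleotide analysis")

    rows = []
    p_global = global_counts / global_counts.sum()
    for d in DINUCLEOTIDE_DATASETS:
        m = joint[d]
        freq = m / m.sum()
        if global_marginals:
            p_first = p_second = p_global
        else:
            p_first = m.sum(axis=1) / m.sum()
            p_second = m.sum(axis=0) / m.sum()
        expected = np.outer(p_first, p_second)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(expected > 0, freq / expected, np.nan)
        for i, bi in enumerate(DNA_BASES):
            for j, bj in enumerate(DNA_BASES):
                rows.append(
                    dict(
                        dataset=d,
                        dinucleotide=dna_to_rna(bi + bj),
                        freq=freq[i, j],
                        ratio=ratio[i, j],
                    )
                )
    return pd.DataFrame(rows)
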