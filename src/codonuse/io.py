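"""Reading, validating and translating coding sequences and expression tables.

A candidate CDS is accepted only if it is at least ``min_length`` nucleotides
long (default 300, the usual transcriptome quality floor), a whole number of
codons, free of ambiguity characters, and free of internal in-frame stop
codons. A single terminal stop codon is permitted; it is stripped from all
downstream codon counting. Rejected sequences are reported with the first
rule they failed, in the fixed order too_short, not_multiple_of_3,
ambiguity, internal_stop.

Expression input is a two-column table (id, FPKM). Rows with FPKM <= 1 are
retained but flagged: expression-stratified analyses use only strictly
FPKM > 1 genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import GeneticCode, STANDARD_CODE, STOP_CODONS

REJECTION_RULES = ("too_short", "not_multiple_of_3", "ambiguity", "internal_stop")


@dataclass(frozen=True)
class CdsRecord:
    """One validated coding sequence.

    ``sequence`` is the full DNA sequence as read (terminal stop included if
    present); ``sense_sequence`` strips the terminal stop and is what every
    downstream statistic counts. ``protein`` has one letter per sense codon.
    """

    id: str
    sequence: str
    protein: str

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def has_terminal_stop(self) -> bool:
        return self.sequence[-3:] in STOP_CODONS

    @property
    def sense_sequence(self) -> str:
        return self.sequence[:-3] if self.has_terminal_stop else self.sequence

    @property
    def n_codons(self) -> int:
        return len(self.sense_sequence) // 3


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _first_failed_rule(
    seq: str, min_length: int, max_internal_stops: int
) -> str | None:
    """Return the first rejection rule a normalized sequence fails, else None."""
    if len(seq) < min_length:
        return "too_short"
    if len(seq) % 3 != 0:
        return "not_multiple_of_3"
    if any(b not in "ACGT" for b in set(seq)):
        return "ambiguity"
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    internal = sum(c in STOP_CODONS for c in codons[:-1])
    if internal > max_internal_stops:
        return "internal_stop"
    return None


def make_cds_record(
    id: str, seq: str, code: GeneticCode = STANDARD_CODE
) -> CdsRecord:
    """Build a CdsRecord from a normalized, already-validated sequence."""
    seq = _normalize(seq)
    sense = seq[:-3] if seq[-3:] in STOP_CODONS else seq
    return CdsRecord(id=id, sequence=seq, protein=code.translate(sense))


def read_cds_fasta(
    path: str | Path,
    min_length: int = 300,
    max_internal_stops: int = 0,
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Read a multi-FASTA of candidate CDSs, returning accepted records and
    a rejection report.

    Parameters
    ----------
    path : FASTA file (nucleotide; T or U, any case).
    min_length : minimum sequence length in nucleotides (inclusive).
    max_internal_stops : internal in-frame stops tolerated before rejection.
        The default 0 rejects any internal stop; downstream RSCU/ENC math
        assumes clean ORFs.

    Returns
    -------
    (records, report) : accepted ``CdsRecord`` list and a DataFrame with
    columns ``id`` and ``rule`` naming the first rule each reject failed.
    """
    path = Path(path)
    records: list[CdsRecord] = []
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()
    n_input = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_input += 1
        rid = rec.id  # header token before first whitespace
        if rid in seen:
            raise ValueError(f"duplicate sequence id: {rid!r}")
        seen.add(rid)
        seq = _normalize(str(rec.seq))
        rule = _first_failed_rule(seq, min_length, max_internal_stops)
        if rule is None:
            records.append(make_cds_record(rid, seq))
        else:
            rejected.append((rid, rule))
    if n_input == 0:
        raise ValueError(f"no sequences in {path}")
    report = pd.DataFrame(rejected, columns=["id", "rule"])
    return records, report


def write_rejection_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


def translate(record: CdsRecord, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a validated CDS; one letter per codon, terminal stop excluded."""
    return code.translate(record.sense_sequence)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a two-column (id, FPKM) table, tab- or whitespace-delimited.

    A header row is detected by a non-numeric second field. Returns a
    DataFrame with columns ``id``, ``fpkm``, ``log10_fpkm`` (NaN when
    FPKM <= 0) and ``above_plot_threshold`` (FPKM strictly above 1).
    """
    path = Path(path)
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"row {lineno} of {path}: expected 2 columns")
            try:
                fpkm = float(parts[1])
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header
                raise ValueError(
                    f"row {lineno} of {path}: non-numeric FPKM {parts[1]!r}"
                ) from None
            if fpkm < 0:
                raise ValueError(f"row {lineno} of {path}: negative FPKM {fpkm}")
            rows.append((parts[0], fpkm))
    df = pd.DataFrame(rows, columns=["id", "fpkm"])
    with np.errstate(divide="ignore"):
        df["log10_fpkm"] = np.where(df["fpkm"] > 0, np.log10(df["fpkm"]), np.nan)
    df["above_plot_threshold"] = df["fpkm"] > 1.0
    return df


def read_gene_set(path: str | Path) -> list[str]:
    """Read a plain-text gene-set file, one id per line; '#' lines ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return ids


def match_expression(
    expression: pd.DataFrame, records: Iterable[CdsRecord]
) -> pd.DataFrame:
    """Warn about expression ids absent from the CDS set; rows are retained."""
    known = {r.id for r in records}
    missing = [i for i in expression["id"] if i not in known]
    if missing:
        warnings.warn(
            f"{len(missing)} expression id(s) absent from the CDS set "
            f"(e.g. {missing[0]!r}); rows retained",
            stacklevel=2,
        )
    return expression
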