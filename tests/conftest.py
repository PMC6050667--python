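from __future__ import annotations

import numpy as np
import pytest

from codonuse import CdsRecord, make_cds_record
from codonuse.genetic_code import SENSE_CODONS

#: One codon per amino acid, covering all 20 (used for the maximal-bias ENC).
ONE_CODON_PER_AA = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_SENSE = np.array(SENSE_CODONS)


def random_record(
    rng: np.random.Generator,
    n_codons: int = 200,
    rec_id: str = "r0",
    start_atg: bool = False,
    terminal_stop: bool = True,
) -> CdsRecord:
    """A record of uniformly random sense codons (never internal stops)."""
    codons = list(_SENSE[rng.integers(0, len(_SENSE), n_codons)])
    if start_atg:
        codons[0] = "ATG"
    seq = "".join(codons) + ("TAA" if terminal_stop else "")
    return make_cds_record(rec_id, seq)


def random_count_table(rng: np.random.Generator, scale: int = 50) -> np.ndarray:
    """A random 64-slot count array with zeros on the stop codons."""
    from codonuse.genetic_code import CODON_INDEX, STOP_CODONS

    counts = rng.integers(0, scale, 64)
    for c in STOP_CODONS:
        counts[CODON_INDEX[c]] = 0
    return counts


def write_fasta(path, entries: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for rid, seq in entries.items():
            fh.write(f">{rid}\n{seq}\n")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20180717)
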