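"""Standard genetic code tables and synonymous-family structure.

All codon-usage statistics in this package are computed under the standard
nuclear genetic code (NCBI translation table 1). The degeneracy structure
follows the classical convention used for Wright's effective number of
codons: leucine, serine and arginine are kept as single six-fold families
(never split 2+4), isoleucine is the only three-fold family, and methionine
and tryptophan are one-codon singletons that carry no synonymous-choice
information.

Sequences are stored as DNA (T) internally; user-facing tables report RNA
codons (U), the convention for transcriptome work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"

#: All 64 DNA codons in lexicographic ACGT order; index = 16*b1 + 4*b2 + b3.
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in DNA_BASES for b in DNA_BASES for c in DNA_BASES
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: Canonical one-letter amino-acid alphabet, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_ncbi = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_ncbi.stop_codons))
CODON_TO_AA: dict[str, str] = dict(_ncbi.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AMINO_ACIDS
}
DEGENERACY: dict[str, int] = {aa: len(v) for aa, v in AA_TO_CODONS.items()}

#: Amino acids grouped by synonymous-family size (2-, 3-, 4- and 6-fold).
FOLD_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(aa for aa in AMINO_ACIDS if DEGENERACY[aa] == k) for k in (2, 3, 4, 6)
}
SINGLET_AAS: tuple[str, ...] = tuple(aa for aa in AMINO_ACIDS if DEGENERACY[aa] == 1)

#: The 59 codons that carry synonymous-choice information: 61 sense codons
#: minus the ATG (Met) and TGG (Trp) singletons.
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] > 1
)

# Byte lookup for fast sequence encoding: A->0, C->1, G->2, T->3, else 255.
_BYTE_LOOKUP = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    _BYTE_LOOKUP[ord(_b)] = _i


def dna_to_rna(codon: str) -> str:
    """Render a DNA codon/sequence in RNA alphabet (T -> U)."""
    return codon.replace("T", "U")


def rna_to_dna(codon: str) -> str:
    """Render an RNA codon/sequence in DNA alphabet (U -> T)."""
    return codon.replace("U", "T")


def encode_bases(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = _BYTE_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        bad = int(np.argmax(arr > 3))
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    return arr


def encode_codons(seq: str) -> np.ndarray:
    """Encode an in-frame A/C/G/T sequence as an array of codon indices."""
    if len(seq) % 3 != 0:
        raise ValueError("sequence length is not a multiple of 3")
    b = encode_bases(seq)
    return (b[0::3].astype(np.intp) * 16 + b[1::3] * 4 + b[2::3])


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code with its synonymous-family structure.

    Attributes
    ----------
    codon_to_aa : mapping of the 61 sense DNA codons to one-letter amino acids.
    families : mapping amino acid -> tuple of its synonymous DNA codons.
    degeneracy : mapping amino acid -> family size (1, 2, 3, 4 or 6).
    stop_codons : the three stop codons.
    """

    codon_to_aa: dict[str, str] = field(default_factory=lambda: dict(CODON_TO_AA))
    families: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(AA_TO_CODONS)
    )
    degeneracy: dict[str, int] = field(default_factory=lambda: dict(DEGENERACY))
    stop_codons: tuple[str, ...] = STOP_CODONS

    def translate(self, seq: str) -> str:
        """Translate an in-frame DNA sequence; stops render as ``*``."""
        if len(seq) % 3 != 0:
            raise ValueError("sequence length is not a multiple of 3")
        return "".join(
            self.codon_to_aa.get(seq[i : i + 3], "*") for i in range(0, len(seq), 3)
        )


STANDARD_CODE = GeneticCode()
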