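"""Independent brute-force oracles, coded separately from the package paths.

These deliberately use plain dict/loop arithmetic and Biopython's codon
table directly, so agreement with the package is a genuine dual-route
check rather than the same code called twice.
"""

from __future__ import annotations

from collections import Counter

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    _FAMILIES.setdefault(_aa, []).append(_codon)


def oracle_codon_tally(seq: str) -> Counter:
    """Sliding-index frame-0 triplet tally."""
    return Counter(seq[i : i + 3] for i in range(0, len(seq) - 2, 3))


def oracle_rscu(counts: dict[str, int]) -> dict[str, float]:
    """RSCU per informative codon: count / (family_total / family_size)."""
    out: dict[str, float] = {}
    for aa, fam in _FAMILIES.items():
        if len(fam) == 1:
            continue
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            continue
        for c in fam:
            out[c] = counts.get(c, 0) / (total / len(fam))
    return out


def oracle_enc(counts: dict[str, int]) -> float | None:
    """Literal Wright estimator with the (F2+F4)/2 fallback for class 3.

    Returns the clamped ENC, or None when undefined.
    """
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in _FAMILIES.items():
        n = len(fam)
        if n == 1:
            continue
        m = sum(counts.get(c, 0) for c in fam)
        if m < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / m) ** 2 for c in fam)
        class_f[n].append((m * sum_p2 - 1.0) / (m - 1.0))
    f_bar = {k: sum(v) / len(v) for k, v in class_f.items() if v}
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    if any(k not in f_bar for k in (2, 3, 4, 6)):
        return None
    if any(f_bar[k] <= 0 for k in (2, 3, 4, 6)):
        return None
    value = 2 + 9 / f_bar[2] + 1 / f_bar[3] + 5 / f_bar[4] + 3 / f_bar[6]
    return min(value, 61.0)


def oracle_dinucleotide_freq(seqs: list[str]) -> dict[str, float]:
    """Pooled overlapping dinucleotide frequencies over a list of strings."""
    tally: Counter = Counter()
    for s in seqs:
        for i in range(len(s) - 1):
            tally[s[i : i + 2]] += 1
    total = sum(tally.values())
    return {d: k / total for d, k in tally.items()}
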