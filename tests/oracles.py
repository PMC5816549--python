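"""Independent brute-force oracles used by the test suite.

Deliberately written without importing the package's own scanning or
counting code: the genetic code is a literal table, motif membership is an
all-substrings test, and the substitution counting is exact rational
arithmetic over explicitly enumerated alternatives and pathways.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import permutations

_BASES_TCAG = "TCAG"
_AA_BY_INDEX = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODE: dict[str, str] = {
    b1 + b2 + b3: _AA_BY_INDEX[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES_TCAG)
    for j, b2 in enumerate(_BASES_TCAG)
    for k, b3 in enumerate(_BASES_TCAG)
}
BASES = "ACGT"


# -- motif oracles ---------------------------------------------------------

def oracle_motif_hits(sequence: str, motif_class: str) -> set[tuple[int, int]]:
    """All (start, end) occurrences of a motif class, by substring testing."""
    n = len(sequence)
    hits: set[tuple[int, int]] = set()
    if motif_class in ("SP3", "SP4", "SP5"):
        k = int(motif_class[2])
        pat = "S" + "P" * k
        for i in range(n - k):
            if sequence[i : i + k + 1] != pat:
                continue
            # a following proline promotes the run to a larger class
            if k < 5 and i + k + 1 < n and sequence[i + k + 1] == "P":
                continue
            hits.add((i, i + k + 1))
    elif motif_class == "PRP_PPV":
        for i in range(n - 4):
            w = sequence[i : i + 5]
            if w[:3] == "PPV" and w[4] in "KC":
                hits.add((i, i + 5))
    elif motif_class == "PRP_KKPCPP":
        for i in range(n - 5):
            if sequence[i : i + 6] == "KKPCPP":
                hits.add((i, i + 6))
    elif motif_class == "LYS_XKK":
        for i in range(n - 2):
            if sequence[i + 1] == "K" and sequence[i + 2] == "K":
                hits.add((i, i + 3))
    elif motif_class == "LYS_KKK":
        for i in range(n - 2):
            if sequence[i : i + 3] == "KKK":
                hits.add((i, i + 3))
    elif motif_class == "LYS_KXK":
        for i in range(n - 2):
            w = sequence[i : i + 3]
            if w[0] == "K" and w[2] == "K" and w[1] != "K":
                hits.add((i, i + 3))
    else:
        raise ValueError(motif_class)
    return hits


# -- NG86 oracle -----------------------------------------------------------

def _oracle_syn_sites(codon: str) -> Fraction:
    total = Fraction(0)
    aa = CODE[codon]
    for pos in range(3):
        alts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in BASES
            if b != codon[pos]
        ]
        alts = [a for a in alts if CODE[a] != "*"]
        if alts:
            syn = sum(1 for a in alts if CODE[a] == aa)
            total += Fraction(syn, len(alts))
    return total


def _oracle_path_counts(ca: str, cb: str) -> tuple[Fraction, Fraction]:
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return Fraction(0), Fraction(0)
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in permutations(diffs):
        sd = nd = 0
        current = ca
        blocked = False
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            if CODE[nxt] == "*":
                blocked = True
            if CODE[current] == CODE[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        (fallback if blocked else valid).append((sd, nd))
    use = valid or fallback
    k = len(use)
    return (
        Fraction(sum(s for s, _ in use), k),
        Fraction(sum(n for _, n in use), k),
    )


def oracle_ng_kaks(seq_a: str, seq_b: str) -> dict:
    """Exact-rational Nei-Gojobori counts with Jukes-Cantor correction."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    codons = [
        (seq_a[i : i + 3], seq_b[i : i + 3]) for i in range(0, len(seq_a), 3)
    ]
    S = (
        sum(_oracle_syn_sites(a) for a, _ in codons)
        + sum(_oracle_syn_sites(b) for _, b in codons)
    ) / 2
    N = 3 * len(codons) - S
    Sd = Fraction(0)
    Nd = Fraction(0)
    for a, b in codons:
        sd, nd = _oracle_path_counts(a, b)
        Sd += sd
        Nd += nd

    def jc(p: Fraction) -> float | None:
        if p >= Fraction(3, 4):
            return None
        return -0.75 * math.log(1.0 - 4.0 * float(p) / 3.0)

    ks = jc(Sd / S) if S > 0 else None
    ka = jc(Nd / N) if N > 0 else None
    return {
        "S": float(S),
        "N": float(N),
        "Sd": float(Sd),
        "Nd": float(Nd),
        "Ks": ks,
        "Ka": ka,
    }


def random_codon_pair(rng, max_codons: int = 30) -> tuple[str, str]:
    """Random stop-free aligned codon pair with scattered substitutions."""
    nonstop = sorted(c for c in CODE if CODE[c] != "*")
    n = int(rng.integers(1, max_codons + 1))
    a_codons = [nonstop[rng.integers(len(nonstop))] for _ in range(n)]
    b_codons = []
    for codon in a_codons:
        derived = codon
        if rng.random() < 0.4:
            while True:
                trial = list(codon)
                for pos in range(3):
                    if rng.random() < 0.5:
                        trial[pos] = BASES[rng.integers(4)]
                candidate = "".join(trial)
                if CODE[candidate] != "*":
                    derived = candidate
                    break
        b_codons.append(derived)
    return "".join(a_codons), "".join(b_codons)
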