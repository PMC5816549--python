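"""Molecular-evolution arithmetic for duplicated gene pairs.

Implements the Nei–Gojobori (1986) pathway-counting Ka/Ks estimator with
Jukes–Cantor multiple-hit correction, Ks-based divergence-time dating
(T = Ks / 2λ) with a recent-WGD window flag, Ks histogramming, the
likelihood-ratio-test arithmetic for nested site-model comparisons, and a
rank/collinearity-based duplicate-gene mode classifier (singleton /
dispersed / proximal / tandem / WGD-or-segmental).

NG86 details that matter for agreement with other implementations:

* The synonymous-site fraction of a codon position is the number of
  synonymous single-base alternatives divided by the number of *non-stop*
  alternatives at that position; stop codons are excluded from the site
  alternatives entirely.
* For codons differing at several positions, the synonymous/nonsynonymous
  difference counts are averaged over all minimal substitution pathways,
  excluding pathways that pass through a stop codon (if every pathway is
  blocked, all pathways are used).
* Site totals S and N are averaged over the two sequences.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

_TABLE = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


class KaKsError(ValueError):
    """Raised for unusable coding-sequence input."""


@dataclass(frozen=True)
class AlignedCdsPair:
    """Two gap-aware aligned coding sequences of equal aligned length."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise KaKsError(
                f"{self.id_a}/{self.id_b}: aligned lengths differ "
                f"({len(self.seq_a)} vs {len(self.seq_b)})"
            )

    def ungapped_codons(self) -> list[tuple[str, str]]:
        """Drop codon columns containing a gap or ambiguous base."""
        a = self.seq_a.upper()
        b = self.seq_b.upper()
        codons = []
        for i in range(0, len(a) - len(a) % 3, 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            if all(x in _BASES for x in ca + cb):
                codons.append((ca, cb))
        return codons


@dataclass(frozen=True)
class KaKsResult:
    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    Ka: float | None
    Ks: float | None
    omega: float | None
    status: str  # ok | saturated | undefined | undefined_omega


@dataclass(frozen=True)
class DivergenceTimeResult:
    Ks: float
    lam: float
    T: float
    in_recent_wgd_window: bool


@dataclass(frozen=True)
class LrtResult:
    lnL_null: float
    lnL_alt: float
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class DuplicationLabel:
    gene_id: str
    mode: str  # singleton | dispersed | proximal | tandem | wgd_segmental


# -- NG86 ------------------------------------------------------------------

def _codon_syn_sites(codon: str) -> float:
    """Synonymous-site count of one codon (0..3), stop-excluded fractions."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            tot += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s


def _pathway_differences(ca: str, cb: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts over minimal pathways."""
    diff_positions = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> tuple[float, float] | None:
        sd = nd = 0.0
        current = ca
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        return sd, nd

    def walk_any(order: Sequence[int]) -> tuple[float, float]:
        sd = nd = 0.0
        current = ca
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            ca_aa = GENETIC_CODE.get(current, "*")
            nx_aa = GENETIC_CODE.get(nxt, "*")
            if ca_aa == nx_aa:
                sd += 1
            else:
                nd += 1
            current = nxt
        return sd, nd

    results = [r for r in map(walk, permutations(diff_positions)) if r is not None]
    if not results:  # every minimal pathway crosses a stop codon
        results = [walk_any(order) for order in permutations(diff_positions)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when the proportion saturates (p >= 3/4)."""
    if p >= 0.75:
        return None
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng_kaks(pair: AlignedCdsPair) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction.

    Codon columns containing gaps or ambiguous bases are dropped; a pair
    with no usable codons is an error.  Saturation (p >= 3/4 on either
    class) and empty site classes are reported through ``status``, never as
    exceptions or infinities.
    """
    codons = pair.ungapped_codons()
    if not codons:
        raise KaKsError(f"{pair.id_a}/{pair.id_b}: no gap-free codon columns")
    for ca, cb in codons:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise KaKsError(
                f"{pair.id_a}/{pair.id_b}: internal stop codon in alignment"
            )

    s_a = sum(_codon_syn_sites(ca) for ca, _ in codons)
    s_b = sum(_codon_syn_sites(cb) for _, cb in codons)
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(codons) - S

    Sd = Nd = 0.0
    for ca, cb in codons:
        sd, nd = _pathway_differences(ca, cb)
        Sd += sd
        Nd += nd

    ps = Sd / S if S > 0.0 else None
    pn = Nd / N if N > 0.0 else None
    Ks = _jukes_cantor(ps) if ps is not None else None
    Ka = _jukes_cantor(pn) if pn is not None else None
    if ps is None or pn is None:
        status = "undefined"
    elif Ks is None or Ka is None:
        status = "saturated"
    elif Ks == 0.0:
        status = "undefined_omega"
    else:
        status = "ok"
    omega = Ka / Ks if status == "ok" else None
    return KaKsResult(pair.id_a, pair.id_b, S, N, Sd, Nd, Ka, Ks, omega, status)


# -- dating, histogram, LRT ------------------------------------------------

def divergence_time(
    ks: float,
    lam: float = 9.1e-9,
    window: tuple[float, float] = (0.15, 0.3),
) -> DivergenceTimeResult:
    """Date a duplication as T = Ks / (2λ), flagging the recent-WGD window.

    The default rate λ = 9.1e-9 synonymous substitutions/site/year and the
    closed window Ks ∈ [0.15, 0.3] correspond to the whole-genome
    duplication shared by pear and apple.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return DivergenceTimeResult(
        Ks=ks,
        lam=lam,
        T=ks / (2.0 * lam),
        in_recent_wgd_window=window[0] <= ks <= window[1],
    )


def ks_histogram(
    ks_values: Iterable[float | None], bin_width: float = 0.05
) -> tuple[dict[int, int], int]:
    """Bin Ks values into half-open bins [k·w, (k+1)·w).

    Values exactly on an edge fall in the upper bin.  None/NaN entries
    (saturated or undefined pairs) are excluded and returned as a separate
    count; bin counts sum to the number of finite inputs.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts: dict[int, int] = defaultdict(int)
    dropped = 0
    for v in ks_values:
        if v is None or not math.isfinite(v):
            dropped += 1
            continue
        counts[int(math.floor(v / bin_width))] += 1
    return dict(counts), dropped


def lrt(lnL_null: float, lnL_alt: float, df: int = 2) -> LrtResult:
    """Likelihood-ratio test: statistic 2·|lnL_alt − lnL_null|, χ² upper tail.

    Built for nested site-model comparisons (e.g. the two-extra-parameter
    beta-plus-omega model against the beta model, df = 2); only the test
    arithmetic lives here, the likelihoods are consumed as input.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    statistic = 2.0 * abs(lnL_alt - lnL_null)
    return LrtResult(
        lnL_null=lnL_null,
        lnL_alt=lnL_alt,
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
    )


# -- duplicate-gene modes --------------------------------------------------

MODES = ("singleton", "dispersed", "proximal", "tandem", "wgd_segmental")


def classify_duplication(
    positions: Sequence,
    homolog_pairs: Iterable[tuple[str, str]],
    collinear_pairs: Iterable[tuple[str, str]] = (),
    proximal_max_rank_gap: int = 10,
) -> dict[str, DuplicationLabel]:
    """Assign one duplication mode to every positioned gene.

    Priority per gene: member of a collinear pair → ``wgd_segmental``;
    homolog at rank distance exactly 1 on the same chromosome → ``tandem``;
    rank distance ≤ ``proximal_max_rank_gap`` → ``proximal``; any other
    homolog → ``dispersed``; no homolog → ``singleton``.  Self-pairs are
    ignored; an unknown gene id in either pair table is an error.
    """
    pos = {p.gene_id: p for p in positions}

    def check(gene: str, table: str) -> None:
        if gene not in pos:
            raise KeyError(f"gene {gene!r} from {table} table has no position")

    homologs: dict[str, set[str]] = defaultdict(set)
    for a, b in homolog_pairs:
        check(a, "homolog")
        check(b, "homolog")
        if a != b:
            homologs[a].add(b)
            homologs[b].add(a)

    collinear_genes: set[str] = set()
    for a, b in collinear_pairs:
        check(a, "collinearity")
        check(b, "collinearity")
        if a != b:
            collinear_genes.update((a, b))

    labels: dict[str, DuplicationLabel] = {}
    for gene, p in pos.items():
        if gene in collinear_genes:
            mode = "wgd_segmental"
        else:
            partners = [pos[h] for h in homologs.get(gene, ())]
            gaps = [
                abs(q.rank - p.rank)
                for q in partners
                if q.chromosome == p.chromosome
            ]
            if any(g == 1 for g in gaps):
                mode = "tandem"
            elif any(1 <= g <= proximal_max_rank_gap for g in gaps):
                mode = "proximal"
            elif partners:
                mode = "dispersed"
            else:
                mode = "singleton"
        labels[gene] = DuplicationLabel(gene, mode)
    return labels


def duplication_mode_counts(labels: Mapping[str, DuplicationLabel]) -> dict[str, int]:
    counts = {mode: 0 for mode in MODES}
    for label in labels.values():
        counts[label.mode] += 1
    return counts
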