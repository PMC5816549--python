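"""Expression divergence of duplicated genes and related utilities.

For a gene pair the expression conservation EC is the Pearson correlation
of the two genes' RPKM vectors across shared samples, and divergence is
1 − EC (in [0, 2]).  The module also draws a seeded random-pair null over a
gene set, compares the divergence distributions by two-sided Wilcoxon
rank-sum tests, performs the symmetric range normalisation used for
heat-map display (log2(v+1) then a per-row affine map onto [−bound, bound]),
and computes relative qPCR expression by the 2^−ΔΔCt rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ExpressionDivergenceResult:
    gene_a: str
    gene_b: str
    ec: float | None
    divergence: float | None
    status: str  # ok | undefined


@dataclass
class DivergenceComparison:
    """Fixed pairs vs a seeded random-pair null vs a user control set."""

    duplicated: list[ExpressionDivergenceResult]
    random: list[ExpressionDivergenceResult]
    control: list[ExpressionDivergenceResult]
    p_values: dict[str, float] = field(default_factory=dict)
    n_dropped_undefined: int = 0

    def divergences(self, which: str) -> np.ndarray:
        results = getattr(self, which)
        return np.array([r.divergence for r in results if r.status == "ok"])


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[1] < 3:
        raise ValueError("expression matrix needs >= 3 samples for correlation")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("RPKM values must be non-negative")


def expression_divergence(
    matrix: pd.DataFrame, gene_a: str, gene_b: str
) -> ExpressionDivergenceResult:
    """Divergence 1 − EC for one gene pair; zero variance → undefined."""
    _validate_matrix(matrix)
    for gene in (gene_a, gene_b):
        if gene not in matrix.index:
            raise KeyError(f"gene {gene!r} absent from the expression matrix")
    a = matrix.loc[gene_a].to_numpy(dtype=float)
    b = matrix.loc[gene_b].to_numpy(dtype=float)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return ExpressionDivergenceResult(gene_a, gene_b, None, None, "undefined")
    ec = float(np.corrcoef(a, b)[0, 1])
    return ExpressionDivergenceResult(gene_a, gene_b, ec, 1.0 - ec, "ok")


def _unrank_pair(index: int, n: int) -> tuple[int, int]:
    """Map a flat index into the lexicographic list of unordered pairs."""
    i = 0
    remaining = index
    row = n - 1
    while remaining >= row:
        remaining -= row
        i += 1
        row -= 1
    return i, i + 1 + remaining


def sample_random_pairs(
    genes: Sequence[str], n_random: int, seed: int
) -> list[tuple[str, str]]:
    """Draw unordered, self-free gene pairs without replacement, seeded."""
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes to form pairs")
    total = n * (n - 1) // 2
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if n_random > total:
        raise ValueError(
            f"n_random={n_random} exceeds the {total} distinct pairs available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=n_random, replace=False)
    return [
        (genes[i], genes[j])
        for i, j in (_unrank_pair(int(c), n) for c in sorted(chosen))
    ]


def divergence_distributions(
    matrix: pd.DataFrame,
    duplicated_pairs: Iterable[tuple[str, str]],
    hrgp_ids: Sequence[str],
    n_random: int,
    seed: int,
    control_pairs: Iterable[tuple[str, str]] = (),
) -> DivergenceComparison:
    """Compare duplicated-pair divergence with a random-pair null.

    Randomly paired genes are drawn uniformly among unordered pairs of
    ``hrgp_ids`` without replacement.  Undefined-status pairs are dropped
    from every sample (counted), and each pair of samples is compared with
    a two-sided Wilcoxon rank-sum test.
    """
    random_pairs = sample_random_pairs(list(hrgp_ids), n_random, seed)
    samples = {
        "duplicated": [expression_divergence(matrix, a, b) for a, b in duplicated_pairs],
        "random": [expression_divergence(matrix, a, b) for a, b in random_pairs],
        "control": [expression_divergence(matrix, a, b) for a, b in control_pairs],
    }
    dropped = sum(
        1 for results in samples.values() for r in results if r.status != "ok"
    )
    comparison = DivergenceComparison(
        duplicated=samples["duplicated"],
        random=samples["random"],
        control=samples["control"],
        n_dropped_undefined=dropped,
    )
    names = ["duplicated", "random", "control"]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x = comparison.divergences(names[i])
            y = comparison.divergences(names[j])
            if len(x) and len(y):
                comparison.p_values[f"{names[i]}_vs_{names[j]}"] = float(
                    stats.ranksums(x, y).pvalue
                )
    return comparison


def normalize_for_heatmap(
    matrix: pd.DataFrame, bound: float = 3.0, mode: str = "range"
) -> pd.DataFrame:
    """Normalise each gene row into [−bound, bound] for heat-map display.

    ``range`` mode (default): v → log2(v+1), then the row's [min, max] is
    mapped affinely onto [−bound, bound].  ``zscore`` mode: per-row z-score
    of log2(v+1) clipped to the bound.  Constant rows map to all zeros.
    """
    if bound <= 0:
        raise ValueError("bound must be positive")
    if mode not in ("range", "zscore"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    logged = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    out = np.zeros_like(logged)
    for i, row in enumerate(logged):
        lo, hi = row.min(), row.max()
        if hi == lo:
            continue
        if mode == "range":
            out[i] = -bound + 2.0 * bound * (row - lo) / (hi - lo)
        else:
            z = (row - row.mean()) / row.std(ddof=1)
            out[i] = np.clip(z, -bound, bound)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression 2^−ΔΔCt from four cycle-threshold values."""
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    delta_delta = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-delta_delta)


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes × samples RPKM TSV (first column = gene id)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    _validate_matrix(matrix)
    return matrix
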