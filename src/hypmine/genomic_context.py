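"""Fixed-window genomic GC content for chromosome display tracks.

Chromosomes are tiled with non-overlapping windows (default 10 kb) from
position 1; the final partial window is kept.  GC is computed over
unambiguous bases only — soft-masked lowercase counts normally, N and other
IUPAC ambiguity codes are excluded from both numerator and denominator, and
an all-ambiguous window carries an undefined-GC flag instead of a value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO


@dataclass(frozen=True)
class GenomeWindow:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    gc_fraction: float | None  # None when the window has no unambiguous base
    n_count: int


def gc_windows_from_sequence(
    chromosome: str, sequence: str, window: int = 10_000
) -> Iterator[GenomeWindow]:
    """Tile one chromosome sequence into GC windows."""
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = sequence.upper()
    for offset in range(0, len(seq), window):
        chunk = seq[offset : offset + window]
        counts = {b: chunk.count(b) for b in "ACGT"}
        unambiguous = sum(counts.values())
        gc = (
            (counts["G"] + counts["C"]) / unambiguous if unambiguous else None
        )
        yield GenomeWindow(
            chromosome=chromosome,
            start=offset + 1,
            end=offset + len(chunk),
            gc_fraction=gc,
            n_count=len(chunk) - unambiguous,
        )


def gc_windows(path: str | Path, window: int = 10_000) -> list[GenomeWindow]:
    """Compute GC windows for every sequence of a nucleotide FASTA."""
    out: list[GenomeWindow] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.extend(gc_windows_from_sequence(rec.id, str(rec.seq), window))
    return out


def write_bed(windows: Iterable[GenomeWindow], path: str | Path) -> None:
    """Write windows as BED4 (0-based half-open; GC in the score column)."""
    with open(path, "w") as fh:
        for w in windows:
            score = "NA" if w.gc_fraction is None else f"{w.gc_fraction:.6f}"
            fh.write(f"{w.chromosome}\t{w.start - 1}\t{w.end}\t{score}\n")
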