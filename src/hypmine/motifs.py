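"""Coordinate-bearing scanners for the hydroxyproline-rich motif classes.

Three motif grammars drive HRGP identification:

* ``SPn`` — one serine followed by exactly *n* prolines (n in {3,4,5}), the
  extensin repeat unit.  A serine followed by a longer proline run is
  reported only under the largest class, so SP3/SP4/SP5 hits are disjoint;
  runs longer than five prolines count as SP5.
* PRP motifs — ``PPV[X][KC]`` (fifth-position alphabet configurable) and the
  literal ``KKPCPP``.
* Lysine motifs — ``[X]KK``, ``KKK`` and ``K[X]K`` windows of length three;
  a *lysine-rich region* is a clustering of such windows.

All patterns are fixed length, so scanning is a plain position loop; hits
carry 0-based half-open coordinates and always satisfy
``matched_text == sequence[start:end]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import RuleConfig
from .seqio import AnnotationTable

SPN_CLASSES = ("SP3", "SP4", "SP5")
PRP_CLASSES = ("PRP_PPV", "PRP_KKPCPP")
LYS_CLASSES = ("LYS_XKK", "LYS_KKK", "LYS_KXK")
MOTIF_CLASSES = SPN_CLASSES + PRP_CLASSES + LYS_CLASSES

#: Longest proline run distinguished after a serine; longer runs fold into it.
MAX_SPN = 5


@dataclass(frozen=True)
class MotifHit:
    motif_class: str
    start: int
    end: int
    matched_text: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("hit coordinates must satisfy 0 <= start < end")
        if len(self.matched_text) != self.end - self.start:
            raise ValueError("matched_text length does not match coordinates")


@dataclass
class MotifProfile:
    """All motif hits for one protein plus per-class counts."""

    protein_id: str
    hits: list[MotifHit] = field(default_factory=list)

    def count(self, motif_class: str) -> int:
        return sum(1 for h in self.hits if h.motif_class == motif_class)

    def counts(self) -> dict[str, int]:
        return {cls: self.count(cls) for cls in MOTIF_CLASSES}

    def of_class(self, *classes: str) -> list[MotifHit]:
        return [h for h in self.hits if h.motif_class in classes]


def _proline_run(sequence: str, i: int) -> int:
    j = i
    while j < len(sequence) and sequence[j] == "P":
        j += 1
    return j - i


def scan_spn(sequence: str, n: int) -> list[MotifHit]:
    """Report every serine followed by exactly ``n`` prolines.

    A serine heading a run of more than ``MAX_SPN`` prolines is reported as
    SP5; intermediate oversized runs (e.g. SPPPP when scanning for SP3)
    belong to the larger class and are not reported here.
    """
    if n not in (3, 4, 5):
        raise ValueError(f"SPn motif order must be 3, 4 or 5, got {n}")
    hits = []
    for i, aa in enumerate(sequence):
        if aa != "S":
            continue
        run = _proline_run(sequence, i + 1)
        if run < 3:
            continue
        if min(run, MAX_SPN) != n:
            continue
        end = i + 1 + n
        hits.append(MotifHit(f"SP{n}", i, end, sequence[i:end]))
    return hits


def scan_prp_motifs(
    sequence: str, fifth_position: Sequence[str] = ("K", "C")
) -> list[MotifHit]:
    """Locate PPV[X][KC] and literal KKPCPP occurrences (overlaps allowed)."""
    allowed = set(fifth_position)
    hits = []
    for i in range(len(sequence) - 4):
        window = sequence[i : i + 5]
        if window.startswith("PPV") and window[4] in allowed:
            hits.append(MotifHit("PRP_PPV", i, i + 5, window))
    for i in range(len(sequence) - 5):
        window = sequence[i : i + 6]
        if window == "KKPCPP":
            hits.append(MotifHit("PRP_KKPCPP", i, i + 6, window))
    return sorted(hits, key=lambda h: (h.start, h.motif_class))


def scan_lysine_motifs(sequence: str) -> list[MotifHit]:
    """Locate [X]KK, KKK and K[X]K windows (all length 3, overlaps allowed).

    The leading residue of [X]KK must exist: a KK at position 0 is not a hit.
    """
    hits = []
    for i in range(len(sequence) - 2):
        window = sequence[i : i + 3]
        if window[1] == "K" and window[2] == "K":
            hits.append(MotifHit("LYS_XKK", i, i + 3, window))
        if window == "KKK":
            hits.append(MotifHit("LYS_KKK", i, i + 3, window))
        if window[0] == "K" and window[2] == "K" and window[1] != "K":
            hits.append(MotifHit("LYS_KXK", i, i + 3, window))
    return hits


def lysine_rich_region_present(
    hits: Iterable[MotifHit], min_hits: int = 2, window: int = 30
) -> bool:
    """True iff >= ``min_hits`` separate lysine-class hits cluster in a window.

    Hits are first reduced greedily to a non-overlapping set so that one
    KKK block (which yields overlapping KKK/[X]KK windows) counts once; the
    window is a span of ``window`` residues measured between hit starts.
    """
    lys = sorted(
        (h for h in hits if h.motif_class in LYS_CLASSES),
        key=lambda h: (h.start, h.end),
    )
    starts: list[int] = []
    cursor = -1
    for hit in lys:
        if hit.start >= cursor:
            starts.append(hit.start)
            cursor = hit.end
    if len(starts) < min_hits:
        return False
    for i in range(len(starts) - min_hits + 1):
        if starts[i + min_hits - 1] - starts[i] < window:
            return True
    return False


def fasciclin_hits(
    annotation: AnnotationTable,
    protein_id: str,
    evalue_cutoff: float = 1e-5,
    accessions: Sequence[str] = ("PF02469",),
) -> bool:
    """True iff a fasciclin-family domain hit passes the E-value cutoff.

    Detection consumes hmmsearch ``--domtblout`` output; with no domain table
    loaded, or the protein absent from it, the answer is False (the caller
    can distinguish "checked and negative" via ``annotation.is_annotated``).
    """
    wanted = {a.split(".")[0] for a in accessions}
    ann = annotation.get(protein_id)
    return any(
        hit.accession in wanted and hit.i_evalue <= evalue_cutoff
        for hit in ann.domain_hits
    )


def scan_all(sequence: str, config: RuleConfig | None = None) -> list[MotifHit]:
    """Scan one sequence for every motif class."""
    cfg = config or RuleConfig()
    hits: list[MotifHit] = []
    for n in (3, 4, 5):
        hits.extend(scan_spn(sequence, n))
    hits.extend(scan_prp_motifs(sequence, cfg.prp_fifth_position))
    hits.extend(scan_lysine_motifs(sequence))
    return sorted(hits, key=lambda h: (h.start, h.end, h.motif_class))


def profile_protein(
    protein_id: str, sequence: str, config: RuleConfig | None = None
) -> MotifProfile:
    return MotifProfile(protein_id, scan_all(sequence, config))
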