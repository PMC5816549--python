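"""Seeded generators of synthetic test data with known ground truth.

Every generator is a pure function of (parameters, seed) and returns a
manifest carrying the planted truth, so recovery statistics can be computed
without re-reading generator internals.

The proteome generator plants one archetype per HRGP subfamily, each built
at least one threshold-width away from every classification boundary:

* AG peptide      — 60–80 aa, 35–45% PAST, motif-free
* classical AGP   — 200–400 aa, 35–45% PAST, motif-free
* lysine-rich AGP — 15–25% PAST plus a clustered pair of KKK motifs
* EXT-AGP         — 15–25% PAST plus two planted SPPP motifs
* FLA             — 15–25% PAST, motif-free, with a synthetic fasciclin
                    (PF02469) domain hit emitted into a companion
                    annotation table
* SP3/SP4/SP5-EXT — <8% PAST plus three planted SPn motifs of the class n
* PRP             — <8% PAST plus two planted PPVAK motifs
* negatives       — uniform background scrubbed of every motif pattern and
                    driven below 8% PAST

PAST content is supplied by Ala/Thr filler and the planted motifs
themselves; backbone residues are drawn from an alphabet that cannot form
any motif (no P, S, K, V or C), which is what makes exact recovery
guarantees possible.  The generators emulate composition and motif
structure only — real proteomes have correlated residue usage, partial
motifs and borderline compositions that these fixtures deliberately avoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evolution import GENETIC_CODE, STOP_CODONS, AlignedCdsPair
from .motifs import scan_all
from .seqio import AnnotationTable, DomainHit, ProteinRecord

#: backbone alphabet: cannot participate in any motif and is not PAST/K
SAFE_BACKGROUND = "GLIFEDRQNHMWY"
PAST_FILLER = "AT"

ARCHETYPES = (
    "AG_PEPTIDE",
    "CLASSICAL_AGP",
    "LYS_RICH_AGP",
    "EXT_AGP",
    "FLA",
    "SP3_EXT",
    "SP4_EXT",
    "SP5_EXT",
    "PRP",
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureManifest:
    """Planted truth for every generated entity."""

    seed: int
    kind: str
    parameters: dict = field(default_factory=dict)
    entries: list[dict] = field(default_factory=list)

    def label_of(self, entity_id: str):
        for entry in self.entries:
            if entry["id"] == entity_id:
                return entry.get("true_label")
        raise KeyError(entity_id)


# -- proteome --------------------------------------------------------------

def _filler(rng: np.random.Generator, n_total: int, n_past: int) -> list[str]:
    n_past = max(0, min(n_past, n_total))
    letters = [PAST_FILLER[rng.integers(2)] for _ in range(n_past)] + [
        SAFE_BACKGROUND[rng.integers(len(SAFE_BACKGROUND))]
        for _ in range(n_total - n_past)
    ]
    rng.shuffle(letters)
    return letters


def _insert_motifs(
    rng: np.random.Generator, filler: list[str], motifs: Sequence[str]
) -> str:
    """Insert motif strings at separated positions inside the filler."""
    if not motifs:
        return "".join(filler)
    # split points leave >= 1 filler residue between consecutive motifs
    n_gaps = len(motifs) + 1
    if len(filler) < len(motifs) - 1:
        raise ValueError("filler too short to separate planted motifs")
    cuts = sorted(rng.choice(len(filler) + 1, size=len(motifs), replace=False))
    out: list[str] = []
    prev = 0
    for cut, motif in zip(cuts, motifs):
        out.append("".join(filler[prev:cut]))
        out.append(motif)
        prev = cut
    out.append("".join(filler[prev:]))
    return "".join(out)


def _build_archetype(
    rng: np.random.Generator, archetype: str
) -> tuple[str, list[str]]:
    """Return (sequence, planted motif strings) for one archetype instance."""
    if archetype == "AG_PEPTIDE":
        length = int(rng.integers(60, 81))
        past = rng.uniform(0.35, 0.45)
        return _insert_motifs(rng, _filler(rng, length, round(past * length)), []), []
    if archetype in ("CLASSICAL_AGP", "FLA"):
        length = int(rng.integers(200, 401))
        past = rng.uniform(0.35, 0.45) if archetype == "CLASSICAL_AGP" else rng.uniform(0.15, 0.25)
        return _insert_motifs(rng, _filler(rng, length, round(past * length)), []), []
    if archetype == "LYS_RICH_AGP":
        length = int(rng.integers(150, 251))
        past = rng.uniform(0.15, 0.25)
        cluster = "KKK" + "".join(
            SAFE_BACKGROUND[rng.integers(len(SAFE_BACKGROUND))] for _ in range(4)
        ) + "KKK"
        seq = _insert_motifs(rng, _filler(rng, length - len(cluster), round(past * length)), [cluster])
        return seq, [cluster]
    if archetype == "EXT_AGP":
        length = int(rng.integers(150, 251))
        past = rng.uniform(0.15, 0.25)
        motifs = ["SPPP", "SPPP"]
        n_past = round(past * length) - 8  # two SPPP contribute 8 PAST residues
        seq = _insert_motifs(rng, _filler(rng, length - 8, n_past), motifs)
        return seq, motifs
    if archetype in ("SP3_EXT", "SP4_EXT", "SP5_EXT"):
        n = int(archetype[2])
        length = int(rng.integers(280, 361))
        motifs = ["S" + "P" * n] * 3
        seq = _insert_motifs(
            rng, _filler(rng, length - 3 * (n + 1), 0), motifs
        )
        return seq, motifs
    if archetype == "PRP":
        length = int(rng.integers(250, 351))
        motifs = ["PPVAK", "PPVAK"]
        seq = _insert_motifs(rng, _filler(rng, length - 10, 0), motifs)
        return seq, motifs
    raise ValueError(f"unknown archetype {archetype!r}")


_SCRUB_OFFSET = {
    "SP3": 0,
    "SP4": 0,
    "SP5": 0,
    "PRP_PPV": 2,
    "PRP_KKPCPP": 3,
    "LYS_XKK": 1,
    "LYS_KKK": 1,
    "LYS_KXK": 0,
}


def _scrub_negative(rng: np.random.Generator, seq: str, max_past: float = 0.06) -> str:
    """Remove every motif occurrence and push PAST below the target.

    Offending residues are replaced with glycine, which cannot participate
    in any motif, so the loop terminates.
    """
    residues = list(seq)
    while True:
        hits = scan_all("".join(residues))
        if not hits:
            break
        hit = hits[0]
        residues[hit.start + _SCRUB_OFFSET[hit.motif_class]] = "G"
    past_positions = [i for i, aa in enumerate(residues) if aa in "PAST"]
    rng.shuffle(past_positions)
    allowed = int(max_past * len(residues))
    for i in past_positions[max(allowed - 1, 0) :]:
        if sum(aa in "PAST" for aa in residues) / len(residues) < max_past:
            break
        residues[i] = SAFE_BACKGROUND[rng.integers(len(SAFE_BACKGROUND))]
    return "".join(residues)


def generate_proteome(
    counts: Mapping[str, int],
    n_negatives: int = 0,
    seed: int = 0,
) -> tuple[list[ProteinRecord], AnnotationTable, FixtureManifest]:
    """Generate a synthetic proteome with planted subfamily archetypes.

    Returns the records, a companion annotation table (synthetic fasciclin
    domain hits for the FLA archetype), and a manifest mapping every id to
    its true subfamily ("NONE" for negatives).
    """
    unknown = set(counts) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")
    if any(v < 0 for v in counts.values()) or n_negatives < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    annotation = AnnotationTable()
    manifest = FixtureManifest(
        seed=seed,
        kind="proteome",
        parameters={"counts": dict(counts), "n_negatives": n_negatives},
    )
    for archetype in ARCHETYPES:
        for i in range(counts.get(archetype, 0)):
            pid = f"syn_{archetype}_{i:04d}"
            seq, motifs = _build_archetype(rng, archetype)
            records.append(ProteinRecord(pid, seq))
            if archetype == "FLA":
                ann = annotation._entry(pid)
                ann.annotated_in.add("domtblout")
                annotation.loaded_sources.add("domtblout")
                start = int(rng.integers(0, max(1, len(seq) - 120)))
                ann.domain_hits.append(
                    DomainHit("PF02469", start, min(start + 110, len(seq)), 1e-10)
                )
            manifest.entries.append(
                {
                    "id": pid,
                    "true_label": archetype,
                    "length": len(seq),
                    "planted_motifs": list(motifs),
                }
            )
    for i in range(n_negatives):
        pid = f"syn_NEG_{i:04d}"
        length = int(rng.integers(100, 301))
        raw = "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(length))
        seq = _scrub_negative(rng, raw)
        records.append(ProteinRecord(pid, seq))
        manifest.entries.append(
            {"id": pid, "true_label": "NONE", "length": len(seq), "planted_motifs": []}
        )
    return records, annotation, manifest


# -- expression ------------------------------------------------------------

def generate_expression(
    n_pairs: int,
    rho: float,
    n_samples: int = 6,
    seed: int = 0,
    log_mean: float = 2.0,
    log_sd: float = 1.0,
) -> tuple[pd.DataFrame, list[tuple[str, str]], FixtureManifest]:
    """Generate paralog-pair RPKM profiles with known log-scale correlation.

    Each pair's per-sample log expression is bivariate normal with
    correlation ``rho`` (log-normal marginals on the RPKM scale, mirroring
    the right-skew of RNA-seq abundance).  The Pearson correlation on the
    RPKM scale is mildly attenuated relative to ``rho``; the manifest
    records the log-scale truth.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    cov = log_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    rows, index, pairs = [], [], []
    for i in range(n_pairs):
        z = rng.multivariate_normal([log_mean, log_mean], cov, size=n_samples)
        a, b = f"pair{i:05d}_a", f"pair{i:05d}_b"
        rows.extend([np.exp(z[:, 0]), np.exp(z[:, 1])])
        index.extend([a, b])
        pairs.append((a, b))
    matrix = pd.DataFrame(
        np.vstack(rows),
        index=index,
        columns=[f"lib{j + 1}" for j in range(n_samples)],
    )
    manifest = FixtureManifest(
        seed=seed,
        kind="expression",
        parameters={
            "n_pairs": n_pairs,
            "rho": rho,
            "n_samples": n_samples,
            "log_mean": log_mean,
            "log_sd": log_sd,
        },
        entries=[{"id": f"pair{i:05d}", "true_label": rho} for i in range(n_pairs)],
    )
    return matrix, pairs, manifest


# -- coding-sequence pairs -------------------------------------------------

_NONSTOP_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)
_BASES = "ACGT"


def _single_base_neighbors(codon: str) -> list[str]:
    out = []
    for pos in range(3):
        for base in _BASES:
            if base != codon[pos]:
                alt = codon[:pos] + base + codon[pos + 1 :]
                if alt not in STOP_CODONS:
                    out.append(alt)
    return out


_SYN_CAPABLE = [
    c
    for c in _NONSTOP_CODONS
    if any(GENETIC_CODE[a] == GENETIC_CODE[c] for a in _single_base_neighbors(c))
]
_NONSYN_CAPABLE = [
    c
    for c in _NONSTOP_CODONS
    if any(GENETIC_CODE[a] != GENETIC_CODE[c] for a in _single_base_neighbors(c))
]


def generate_cds_pair(
    n_codons: int,
    n_syn: int,
    n_nonsyn: int,
    seed: int = 0,
    id_a: str = "cds_a",
    id_b: str = "cds_b",
) -> tuple[AlignedCdsPair, FixtureManifest]:
    """Generate an aligned codon pair with planted substitution classes.

    A stop-free ancestor is sampled; exactly ``n_syn`` synonymous and
    ``n_nonsyn`` nonsynonymous single-base edits are applied to distinct
    codons of one copy (codons at edit positions are drawn from codons that
    admit the requested edit class without creating a stop).
    """
    if n_syn < 0 or n_nonsyn < 0:
        raise ValueError("edit counts must be non-negative")
    if n_syn + n_nonsyn > n_codons:
        raise ValueError(
            f"cannot place {n_syn}+{n_nonsyn} edits in {n_codons} codons"
        )
    rng = np.random.default_rng(seed)
    ancestor = [
        _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))] for _ in range(n_codons)
    ]
    edit_sites = rng.choice(n_codons, size=n_syn + n_nonsyn, replace=False)
    derived = list(ancestor)
    for k, site in enumerate(edit_sites):
        synonymous = k < n_syn
        pool = _SYN_CAPABLE if synonymous else _NONSYN_CAPABLE
        codon = pool[rng.integers(len(pool))]
        ancestor[site] = codon
        wanted = [
            alt
            for alt in _single_base_neighbors(codon)
            if (GENETIC_CODE[alt] == GENETIC_CODE[codon]) == synonymous
        ]
        derived[site] = wanted[rng.integers(len(wanted))]
    pair = AlignedCdsPair(id_a, id_b, "".join(ancestor), "".join(derived))
    manifest = FixtureManifest(
        seed=seed,
        kind="cds_pair",
        parameters={"n_codons": n_codons, "n_syn": n_syn, "n_nonsyn": n_nonsyn},
        entries=[
            {
                "id": f"{id_a}|{id_b}",
                "true_label": {"n_syn": n_syn, "n_nonsyn": n_nonsyn},
            }
        ],
    )
    return pair, manifest


# -- genome ----------------------------------------------------------------

def generate_genome(
    chromosome_lengths: Mapping[str, int],
    gc: float = 0.4,
    seed: int = 0,
) -> tuple[dict[str, str], FixtureManifest]:
    """Generate chromosome sequences with a target GC composition."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    chroms = {}
    manifest = FixtureManifest(
        seed=seed, kind="genome", parameters={"gc": gc}
    )
    for name, length in chromosome_lengths.items():
        draws = rng.choice(4, size=length, p=probs)
        seq = "".join("AGCT"[d] for d in draws)
        chroms[name] = seq
        realized = (seq.count("G") + seq.count("C")) / length if length else None
        manifest.entries.append(
            {"id": name, "true_label": gc, "length": length, "realized_gc": realized}
        )
    return chroms, manifest
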