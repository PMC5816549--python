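"""Biased-composition + motif classification of HRGP families.

The superfamily splits into arabinogalactan-proteins (AGP), extensins (EXT)
and proline-rich proteins (PRP).  Every protein is pushed through an ordered
first-match-wins rule cascade built from its PAST fraction (the proportion
of Pro/Ala/Ser/Thr residues), its motif profile and its consumed domain
annotations:

1. FLA            fasciclin domain hit and PAST >= past_agp
2. EXT_AGP        PAST >= past_agp and at least one SPn hit
3. LYS_RICH_AGP   PAST >= past_agp and a lysine-rich region
4. AG_PEPTIDE     PAST >= past_agp and length <= ag_peptide_max_len
5. CLASSICAL_AGP  PAST >= past_classical and no swapped (non-fasciclin)
                  domain when a domain table is loaded
6. SPn_EXT        >= min_ext_hits SPn hits (largest n with enough hits wins)
7. PRP            any PPV[X][KC] or KKPCPP hit
8. NONE           otherwise

The cascade order is configurable; NONE is a valid verdict, so the classes
always partition the proteome.  Signal-peptide and GPI flags are copied from
the annotation table and never change a call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import RuleConfig
from .motifs import (
    LYS_CLASSES,
    MotifProfile,
    fasciclin_hits,
    lysine_rich_region_present,
    profile_protein,
)
from .seqio import AnnotationTable, ProteinRecord

PAST_RESIDUES = frozenset("PAST")

FAMILY_OF_SUBFAMILY = {
    "AG_PEPTIDE": "AGP",
    "LYS_RICH_AGP": "AGP",
    "FLA": "AGP",
    "EXT_AGP": "AGP",
    "CLASSICAL_AGP": "AGP",
    "SP3_EXT": "EXT",
    "SP4_EXT": "EXT",
    "SP5_EXT": "EXT",
    "PRP": "PRP",
    "NONE": "NONE",
}

#: presentation order for the summary table
SUBFAMILY_ORDER = (
    "SP3_EXT",
    "SP4_EXT",
    "SP5_EXT",
    "EXT_AGP",
    "AG_PEPTIDE",
    "LYS_RICH_AGP",
    "FLA",
    "CLASSICAL_AGP",
    "PRP",
    "NONE",
)


@dataclass(frozen=True)
class CompositionProfile:
    """Per-protein P/A/S/T (and K) counts and the PAST fraction."""

    protein_id: str
    length: int
    p: int
    a: int
    s: int
    t: int
    k: int

    @property
    def past_fraction(self) -> float:
        return (self.p + self.a + self.s + self.t) / self.length


@dataclass
class HrgpCall:
    protein_id: str
    family: str
    subfamily: str
    evidence: dict = field(default_factory=dict)
    has_signal_peptide: bool = False
    has_gpi_anchor: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if FAMILY_OF_SUBFAMILY[self.subfamily] != self.family:
            raise ValueError(
                f"subfamily {self.subfamily} inconsistent with family {self.family}"
            )


def compute_composition(record: ProteinRecord) -> CompositionProfile:
    """Count P/A/S/T/K residues; ambiguous letters (X/B/Z/U) never count."""
    seq = record.sequence
    if not seq:
        raise ValueError(f"empty sequence for {record.id}")
    return CompositionProfile(
        record.id,
        record.length,
        seq.count("P"),
        seq.count("A"),
        seq.count("S"),
        seq.count("T"),
        seq.count("K"),
    )


def _spn_subfamily(motifs: MotifProfile, cfg: RuleConfig) -> str | None:
    counts = {n: motifs.count(f"SP{n}") for n in (3, 4, 5)}
    if cfg.ext_same_n:
        for n in (5, 4, 3):
            if counts[n] >= cfg.min_ext_hits:
                return f"SP{n}_EXT"
        return None
    if sum(counts.values()) >= cfg.min_ext_hits:
        for n in (5, 4, 3):
            if counts[n] > 0:
                return f"SP{n}_EXT"
    return None


def classify_protein(
    profile: CompositionProfile,
    motifs: MotifProfile,
    annotation: AnnotationTable,
    config: RuleConfig | None = None,
) -> HrgpCall:
    """Apply the ordered rule cascade to one protein."""
    cfg = config or RuleConfig()
    if profile.protein_id != motifs.protein_id:
        raise ValueError("composition and motif profiles refer to different proteins")

    past = profile.past_fraction
    ann = annotation.get(profile.protein_id)
    fla = fasciclin_hits(
        annotation, profile.protein_id, cfg.fla_evalue, cfg.fla_accessions
    )
    lys_region = lysine_rich_region_present(
        motifs.of_class(*LYS_CLASSES), cfg.lys_min_hits, cfg.lys_window
    )
    n_spn = sum(motifs.count(f"SP{n}") for n in (3, 4, 5))
    n_prp = motifs.count("PRP_PPV") + motifs.count("PRP_KKPCPP")

    flags: list[str] = []
    if not annotation.is_annotated(profile.protein_id):
        flags.append("not-annotated")

    subfamily = "NONE"
    for rule in cfg.rule_order:
        if rule == "FLA" and fla and past >= cfg.past_agp:
            subfamily = "FLA"
        elif rule == "EXT_AGP" and past >= cfg.past_agp and n_spn >= 1:
            subfamily = "EXT_AGP"
        elif rule == "LYS_RICH_AGP" and past >= cfg.past_agp and lys_region:
            subfamily = "LYS_RICH_AGP"
        elif (
            rule == "AG_PEPTIDE"
            and past >= cfg.past_agp
            and profile.length <= cfg.ag_peptide_max_len
        ):
            subfamily = "AG_PEPTIDE"
        elif rule == "CLASSICAL_AGP" and past >= cfg.past_classical:
            if annotation.has_domain_table:
                swapped = [
                    h
                    for h in ann.domain_hits
                    if h.accession not in set(cfg.fla_accessions)
                ]
                if swapped:
                    continue
            else:
                flags.append("domain-check-skipped")
            subfamily = "CLASSICAL_AGP"
        elif rule == "SPN_EXT":
            sub = _spn_subfamily(motifs, cfg)
            if sub is None:
                continue
            subfamily = sub
        elif rule == "PRP" and n_prp >= 1:
            subfamily = "PRP"
        else:
            continue
        break
    if subfamily != "CLASSICAL_AGP" and "domain-check-skipped" in flags:
        flags.remove("domain-check-skipped")

    return HrgpCall(
        protein_id=profile.protein_id,
        family=FAMILY_OF_SUBFAMILY[subfamily],
        subfamily=subfamily,
        evidence={
            "past_fraction": past,
            "length": profile.length,
            "motif_counts": motifs.counts(),
            "fasciclin": fla,
            "lysine_region": lys_region,
        },
        has_signal_peptide=ann.has_signal_peptide,
        has_gpi_anchor=ann.has_gpi_anchor,
        flags=flags,
    )


def classify_proteome(
    records: list[ProteinRecord],
    annotation: AnnotationTable | None = None,
    config: RuleConfig | None = None,
) -> list[HrgpCall]:
    """Profile and classify every record of a proteome."""
    cfg = config or RuleConfig()
    ann = annotation or AnnotationTable()
    calls = []
    for rec in records:
        comp = compute_composition(rec)
        prof = profile_protein(rec.id, rec.sequence, cfg)
        calls.append(classify_protein(comp, prof, ann, cfg))
    return calls


def summarize_calls(calls: list[HrgpCall]) -> pd.DataFrame:
    """Aggregate calls into a per-subfamily SP/GPI/total summary table.

    One row per subfamily (NONE included only when present), then one total
    row per family and a grand total over the three HRGP families.
    """
    rows = []
    for sub in SUBFAMILY_ORDER:
        members = [c for c in calls if c.subfamily == sub]
        if sub == "NONE" and not members:
            continue
        rows.append(
            {
                "family": FAMILY_OF_SUBFAMILY[sub],
                "subfamily": sub,
                "with_sp": sum(c.has_signal_peptide for c in members),
                "with_gpi": sum(c.has_gpi_anchor for c in members),
                "total": len(members),
            }
        )
    for fam in ("EXT", "AGP", "PRP"):
        members = [c for c in calls if c.family == fam]
        rows.append(
            {
                "family": fam,
                "subfamily": "ALL",
                "with_sp": sum(c.has_signal_peptide for c in members),
                "with_gpi": sum(c.has_gpi_anchor for c in members),
                "total": len(members),
            }
        )
    hrgps = [c for c in calls if c.family != "NONE"]
    rows.append(
        {
            "family": "TOTAL",
            "subfamily": "ALL",
            "with_sp": sum(c.has_signal_peptide for c in hrgps),
            "with_gpi": sum(c.has_gpi_anchor for c in hrgps),
            "total": len(hrgps),
        }
    )
    return pd.DataFrame(rows, columns=["family", "subfamily", "with_sp", "with_gpi", "total"])


def validate_by_homology(
    calls: list[HrgpCall],
    candidate_hits: list[tuple[str, str, float, float]] | None = None,
    borderline: tuple[float, float] = (0.08, 0.12),
    min_identity: float = 30.0,
    max_evalue: float = 1e-5,
) -> list[HrgpCall]:
    """Flag borderline-PAST calls, optionally marking homology support.

    A call whose PAST fraction falls inside ``borderline`` gets a
    "borderline" flag; when a candidate-vs-known-HRGP BLAST table is given,
    a supporting hit (identity >= ``min_identity``, E <= ``max_evalue``)
    additionally sets "homology-supported".  No call is ever changed.
    """
    supported: set[str] = set()
    if candidate_hits is not None:
        for query, _subject, identity, evalue in candidate_hits:
            if identity >= min_identity and evalue <= max_evalue:
                supported.add(query)
    for call in calls:
        past = call.evidence.get("past_fraction")
        if past is not None and borderline[0] <= past <= borderline[1]:
            if "borderline" not in call.flags:
                call.flags.append("borderline")
            if call.protein_id in supported and "homology-supported" not in call.flags:
                call.flags.append("homology-supported")
    return calls


def calls_to_dataframe(calls: list[HrgpCall]) -> pd.DataFrame:
    """Flatten calls into the TSV layout written by the CLI."""
    rows = []
    for c in calls:
        counts = c.evidence.get("motif_counts", {})
        rows.append(
            {
                "protein_id": c.protein_id,
                "family": c.family,
                "subfamily": c.subfamily,
                "past_fraction": round(c.evidence.get("past_fraction", float("nan")), 4),
                "length": c.evidence.get("length"),
                "sp3": counts.get("SP3", 0),
                "sp4": counts.get("SP4", 0),
                "sp5": counts.get("SP5", 0),
                "prp_ppv": counts.get("PRP_PPV", 0),
                "prp_kkpcpp": counts.get("PRP_KKPCPP", 0),
                "lys": sum(counts.get(k, 0) for k in LYS_CLASSES),
                "has_SP": c.has_signal_peptide,
                "has_GPI": c.has_gpi_anchor,
                "flags": ";".join(c.flags),
            }
        )
    return pd.DataFrame(rows)
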