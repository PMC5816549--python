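"""Readers, writers and record normalisation for the formats the tool touches.

Protein and nucleotide FASTA go through Biopython.  The gene-position reader
auto-detects plain GFF3 versus the four-column ``chrom gene start end``
dialect used by MCScanX.  SignalP 4 "short" tables, big-PI output, hmmsearch
``--domtblout`` tables, 12-column BLAST tabular hits and MCScanX
``.collinearity`` blocks are parsed by the documented column/keyword rules
below; none of the upstream programs is ever executed here.

Coordinate conventions: motif/domain coordinates are 0-based half-open
internally; genomic positions stay 1-based inclusive as in GFF.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class SeqIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: stable identifier plus amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise SeqIOError(f"empty sequence for record {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenePosition:
    """A gene's genomic placement with a dense per-chromosome rank."""

    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SeqIOError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class DomainHit:
    accession: str
    env_start: int  # 0-based half-open on the protein
    env_end: int
    i_evalue: float


@dataclass
class GeneAnnotation:
    has_signal_peptide: bool = False
    sp_cleavage_site: int | None = None
    has_gpi_anchor: bool = False
    domain_hits: list[DomainHit] = field(default_factory=list)
    #: which of the three upstream tables actually mentioned this gene
    annotated_in: set[str] = field(default_factory=set)


class AnnotationTable:
    """Per-gene SP/GPI/domain annotations merged from upstream predictors.

    A gene absent from every loaded table reports ``has_signal_peptide`` and
    ``has_gpi_anchor`` as False but is flagged ``not annotated`` via
    :meth:`is_annotated`, so silence is visible rather than a hard negative.
    """

    def __init__(self) -> None:
        self._genes: dict[str, GeneAnnotation] = {}
        self.loaded_sources: set[str] = set()

    def _entry(self, gene_id: str) -> GeneAnnotation:
        return self._genes.setdefault(gene_id, GeneAnnotation())

    def get(self, gene_id: str) -> GeneAnnotation:
        return self._genes.get(gene_id, GeneAnnotation())

    def is_annotated(self, gene_id: str, source: str | None = None) -> bool:
        ann = self._genes.get(gene_id)
        if ann is None:
            return False
        return bool(ann.annotated_in) if source is None else source in ann.annotated_in

    def genes(self) -> Iterable[str]:
        return self._genes.keys()

    @property
    def has_domain_table(self) -> bool:
        return "domtblout" in self.loaded_sources

    # -- upstream table loaders -------------------------------------------

    def load_signalp_short(self, path: str | Path) -> "AnnotationTable":
        """Parse a SignalP 4 "short" table.

        Column rule: field 1 = sequence id, field 3 = Cmax position (taken as
        the cleavage site when positive), field 10 = the Y/N signal-peptide
        verdict.
        """
        self.loaded_sources.add("signalp")
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 10:
                    raise SeqIOError(
                        f"{path}: line {lineno}: expected >=10 SignalP columns"
                    )
                ann = self._entry(fields[0])
                ann.annotated_in.add("signalp")
                ann.has_signal_peptide = fields[9].upper() == "Y"
                if ann.has_signal_peptide:
                    try:
                        ann.sp_cleavage_site = int(fields[2])
                    except ValueError as exc:
                        raise SeqIOError(
                            f"{path}: line {lineno}: bad Cmax position"
                        ) from exc
        return self

    def load_bigpi(self, path: str | Path) -> "AnnotationTable":
        """Parse big-PI textual output.

        Keyword rule: a ``Query: <id>`` (or ``Sequence: <id>``) line opens a
        block; a later line containing ``Potential GPI-modification site``
        marks the gene GPI-anchored, one containing ``No GPI-modification
        site`` marks it negative.
        """
        self.loaded_sources.add("bigpi")
        current: str | None = None
        with open(path) as fh:
            for line in fh:
                stripped = line.strip()
                if stripped.startswith(("Query:", "Sequence:")):
                    current = stripped.split(":", 1)[1].split()[0]
                    ann = self._entry(current)
                    ann.annotated_in.add("bigpi")
                elif current is not None:
                    if "Potential GPI-modification site" in stripped:
                        self._entry(current).has_gpi_anchor = True
                    elif "No GPI-modification site" in stripped:
                        self._entry(current).has_gpi_anchor = False
        return self

    def load_domtblout(
        self, path: str | Path, lengths: Mapping[str, int] | None = None
    ) -> "AnnotationTable":
        """Parse hmmsearch ``--domtblout`` (whitespace-delimited, ``#`` skipped).

        Target name (field 1) is the protein; the query accession (field 5,
        falling back to the query name when "-") identifies the domain; the
        independent E-value is field 13 and the envelope is fields 20-21
        (1-based inclusive, stored half-open).
        """
        self.loaded_sources.add("domtblout")
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 21:
                    raise SeqIOError(
                        f"{path}: line {lineno}: expected >=21 domtblout columns"
                    )
                target = fields[0]
                accession = fields[4] if fields[4] != "-" else fields[3]
                accession = accession.split(".")[0]
                try:
                    i_evalue = float(fields[12])
                    env_from, env_to = int(fields[19]), int(fields[20])
                except ValueError as exc:
                    raise SeqIOError(
                        f"{path}: line {lineno}: bad numeric field"
                    ) from exc
                if lengths is not None and target in lengths:
                    if env_to > lengths[target]:
                        raise SeqIOError(
                            f"{path}: line {lineno}: envelope end {env_to} "
                            f"exceeds length of {target}"
                        )
                ann = self._entry(target)
                ann.annotated_in.add("domtblout")
                ann.domain_hits.append(
                    DomainHit(accession, env_from - 1, env_to, i_evalue)
                )
        return self


def write_domtblout(table: AnnotationTable, path: str | Path) -> None:
    """Write domain hits back out in hmmsearch ``--domtblout`` layout.

    Only the fields this package consumes are meaningful; the remaining
    columns are filled with placeholders so any standard parser accepts
    the file.
    """
    with open(path, "w") as fh:
        fh.write("# target acc tlen query qacc qlen E score bias n of "
                 "cE iE dscore dbias hf ht af at ef et acc desc\n")
        for gene in sorted(table.genes()):
            for hit in table.get(gene).domain_hits:
                env_from, env_to = hit.env_start + 1, hit.env_end
                fh.write(
                    f"{gene} - 0 {hit.accession} {hit.accession}.0 0 "
                    f"{hit.i_evalue:g} 0.0 0.0 1 1 {hit.i_evalue:g} "
                    f"{hit.i_evalue:g} 0.0 0.0 1 1 {env_from} {env_to} "
                    f"{env_from} {env_to} 0.99 -\n"
                )


# -- proteome FASTA --------------------------------------------------------

def read_proteome(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased, a single trailing stop symbol ``*`` is
    stripped, and the id is everything before the first whitespace.
    Duplicate ids and empty files are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise SeqIOError(f"no records in {path}")
    return records


def write_proteome(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def collapse_repetitive(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], dict[str, list[str]]]:
    """Collapse exact amino-acid duplicates to one representative each.

    The representative is the lexicographically smallest id of its group;
    every removed id is reported under that representative.  Input order is
    preserved among the retained records.
    """
    groups: dict[str, list[ProteinRecord]] = defaultdict(list)
    for rec in records:
        groups[rec.sequence].append(rec)
    keep: dict[str, ProteinRecord] = {}
    report: dict[str, list[str]] = {}
    for seq, members in groups.items():
        rep = min(members, key=lambda r: r.id)
        keep[seq] = rep
        removed = sorted(r.id for r in members if r.id != rep.id)
        if removed:
            report[rep.id] = removed
    retained = [keep[rec.sequence] for rec in records if keep[rec.sequence].id == rec.id]
    return retained, report


# -- gene positions --------------------------------------------------------

def _assign_ranks(
    rows: list[tuple[str, str, int, int]]
) -> list[GenePosition]:
    by_chrom: dict[str, list[tuple[str, str, int, int]]] = defaultdict(list)
    for row in rows:
        by_chrom[row[1]].append(row)
    out: list[GenePosition] = []
    for chrom in by_chrom:
        ordered = sorted(by_chrom[chrom], key=lambda r: (r[2], r[0]))
        for rank, (gene, chrom_, start, end) in enumerate(ordered):
            out.append(GenePosition(gene, chrom_, start, end, rank))
    return out


def read_gene_positions(path: str | Path) -> list[GenePosition]:
    """Read gene positions from GFF3 or the MCScanX four-column gff dialect.

    Dialect is auto-detected per file: four tab-separated columns
    ``chrom gene start end`` means MCScanX; nine columns means GFF3, where
    gene ids come from the ``ID=`` attribute of gene/mRNA features.  Ranks
    are dense 0-based per chromosome, ordered by start then gene id.
    """
    rows: list[tuple[str, str, int, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 4:
                    chrom, gene, start, end = fields
                    rows.append((gene.strip(), chrom.strip(), int(start), int(end)))
                elif len(fields) == 9:
                    if fields[2] not in ("gene", "mRNA"):
                        continue
                    attrs = dict(
                        kv.split("=", 1)
                        for kv in fields[8].split(";")
                        if "=" in kv
                    )
                    gene = attrs.get("ID")
                    if gene is None:
                        raise ValueError("missing ID attribute")
                    rows.append((gene, fields[0], int(fields[3]), int(fields[4])))
                else:
                    raise ValueError(
                        f"expected 4 (MCScanX) or 9 (GFF3) columns, got {len(fields)}"
                    )
            except ValueError as exc:
                raise SeqIOError(f"{path}: line {lineno}: {exc}") from exc
    # mRNA records in GFF3 may duplicate a gene id; keep the first occurrence
    deduped = []
    for row in rows:
        if row[0] not in seen:
            seen.add(row[0])
            deduped.append(row)
    return _assign_ranks(deduped)


# -- homology and collinearity inputs --------------------------------------

def read_blast_pairs(path: str | Path) -> list[tuple[str, str, float, float]]:
    """Read 12-column BLAST tabular hits.

    Returns (query, subject, percent identity, E-value) tuples; self-hits
    are retained here and filtered by consumers that need to.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                fields = line.split()
            if len(fields) < 12:
                raise SeqIOError(
                    f"{path}: line {lineno}: expected 12 BLAST tabular columns"
                )
            try:
                pairs.append(
                    (fields[0], fields[1], float(fields[2]), float(fields[10]))
                )
            except ValueError as exc:
                raise SeqIOError(f"{path}: line {lineno}: {exc}") from exc
    return pairs


def read_collinearity(path: str | Path) -> list[tuple[str, str]]:
    """Read gene pairs from an MCScanX ``.collinearity`` file.

    Header/comment lines start with ``#``; pair lines look like
    ``  0-  1:\tgeneA\tgeneB\t  1e-50`` — everything after the first colon is
    split on whitespace and the first two tokens are the pair.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if ":" not in line:
                continue
            tail = line.split(":", 1)[1].split()
            if len(tail) < 2:
                raise SeqIOError(
                    f"{path}: line {lineno}: malformed collinearity pair line"
                )
            pairs.append((tail[0], tail[1]))
    return pairs


def read_aligned_pairs(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Read consecutive two-record aligned FASTA blocks.

    Returns (id_a, id_b, aligned_seq_a, aligned_seq_b) per block; an odd
    number of records is an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqIOError(f"no records in {path}")
    if len(records) % 2:
        raise SeqIOError(
            f"{path}: aligned pair file holds an odd number of records"
        )
    out = []
    for i in range(0, len(records), 2):
        a, b = records[i], records[i + 1]
        out.append((a.id, b.id, str(a.seq).upper(), str(b.seq).upper()))
    return out
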