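"""Readers and writers for the pipeline's external formats.

Everything downstream works on the in-memory types defined here: a
:class:`Proteome` of :class:`ProteinRecord` objects, validated
:class:`SiteRecord` phosphosites, protein-to-GO-term annotation tables, and
homolog-mapping tables carrying center-aligned 13-residue windows.

Positions are 1-based everywhere in external tables, matching the convention
of phosphosite databases; window offsets (elsewhere) are signed integers with
0 at the site itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard amino acids
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguity/nonstandard letters tolerated in input sequences but never
#: counted as Met/hydrophobic and excluded from hydropathy averaging
AMBIGUOUS_AA = "BZXU"

VALID_RESIDUES = {"S", "T", "Y"}
VALID_EVIDENCE = {"experimental", "predicted", "all_sty"}
VALID_NAMESPACES = {"BP", "MF", "CC"}

WINDOW_LEN = 13  # center-aligned homolog windows are always 13 residues


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier plus an uppercase amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(STANDARD_AA) - set(AMBIGUOUS_AA)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )
        if set(self.sequence) & set(AMBIGUOUS_AA):
            logger.debug("protein %s contains ambiguity letters", self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """A collection of proteins with unique ids; the universe for counting."""

    records: list[ProteinRecord]
    taxon_label: str = "unknown"
    kingdom_group: str = "plant"

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate protein id {dup!r} in proteome")
        self._index = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self._index[protein_id]


@dataclass(frozen=True)
class SiteRecord:
    """A phosphorylatable Ser/Thr/Tyr site in a protein.

    ``position`` is 1-based; ``evidence`` is ``experimental``, ``predicted``,
    or ``all_sty`` for proteome-wide background sites.
    """

    protein_id: str
    position: int
    residue: str
    evidence: str = "experimental"

    def __post_init__(self):
        if self.residue not in VALID_RESIDUES:
            raise ValueError(f"residue must be S/T/Y, got {self.residue!r}")
        if self.evidence not in VALID_EVIDENCE:
            raise ValueError(f"unknown evidence class {self.evidence!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")

    def validate(self, proteome: Proteome) -> None:
        """Check the site against the proteome; raise on mismatch."""
        if self.protein_id not in proteome:
            raise KeyError(f"protein {self.protein_id!r} not in proteome")
        seq = proteome[self.protein_id].sequence
        if self.position > len(seq):
            raise ValueError(
                f"site {self.protein_id}:{self.position} beyond sequence "
                f"length {len(seq)}"
            )
        if seq[self.position - 1] != self.residue:
            raise ValueError(
                f"site {self.protein_id}:{self.position} claims "
                f"{self.residue} but sequence has {seq[self.position - 1]}"
            )


@dataclass
class GOAnnotationTable:
    """protein_id -> set of (term_id, namespace) annotations."""

    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, protein_id: str, term_id: str, namespace: str) -> None:
        if namespace not in VALID_NAMESPACES:
            raise ValueError(f"namespace must be one of BP/MF/CC, got {namespace!r}")
        self.entries.setdefault(protein_id, set()).add((term_id, namespace))

    def terms_of(self, protein_id: str) -> set[tuple[str, str]]:
        return self.entries.get(protein_id, set())


@dataclass(frozen=True)
class HomologMappingRow:
    """One aligned 13-residue window for a (query site, taxon) pair."""

    query_protein_id: str
    query_position: int
    taxon_label: str
    aligned_window: str

    def __post_init__(self):
        if len(self.aligned_window) != WINDOW_LEN:
            raise ValueError(
                f"aligned window must be {WINDOW_LEN} characters, got "
                f"{len(self.aligned_window)}"
            )


@dataclass
class HomologMappingTable:
    rows: list[HomologMappingRow] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, taxon_label: str = "unknown",
               kingdom_group: str = "plant") -> Proteome:
    """Read a FASTA proteome.

    The header token before the first whitespace becomes the protein id;
    sequences are uppercased. A single trailing ``*`` (stop) is stripped with
    a warning. Duplicate ids, empty files, and letters outside the standard
    alphabet plus B/Z/X/U are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            logger.warning("stripping trailing stop '*' from %s", pid)
            seq = seq[:-1]
        if "*" in seq:
            raise ValueError(f"internal stop codon '*' in {pid!r}")
        records.append(ProteinRecord(id=pid, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Proteome(records=records, taxon_label=taxon_label,
                    kingdom_group=kingdom_group)


def write_fasta(proteome: Proteome, path: str | Path) -> None:
    """Write a proteome to FASTA (round-trips with :func:`read_fasta`)."""
    recs = [SeqRecord(Seq(r.sequence), id=r.id, description="")
            for r in proteome]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Site tables

SITE_COLUMNS = ["protein_id", "position", "residue", "evidence"]


def read_site_table(path: str | Path, proteome: Proteome) -> list[SiteRecord]:
    """Read a 4-column TSV of phosphosites and validate against the proteome.

    Rows whose protein is absent or whose residue does not match the sequence
    are rejected and logged; a malformed position is a hard error. Returns
    the accepted records.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} missing columns {missing}")
    accepted: list[SiteRecord] = []
    rejected = 0
    for row in df.itertuples(index=False):
        try:
            pos = int(row.position)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed position {row.position!r} in {path}") from exc
        try:
            site = SiteRecord(protein_id=row.protein_id, position=pos,
                              residue=row.residue, evidence=row.evidence)
            site.validate(proteome)
        except (ValueError, KeyError) as exc:
            logger.info("rejecting site row: %s", exc)
            rejected += 1
            continue
        accepted.append(site)
    if rejected:
        logger.warning("site table %s: accepted %d rows, rejected %d",
                       path, len(accepted), rejected)
    return accepted


def write_site_table(sites: Iterable[SiteRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.protein_id, s.position, s.residue, s.evidence) for s in sites],
        columns=SITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def enumerate_all_sty(proteome: Proteome) -> list[SiteRecord]:
    """One ``all_sty`` SiteRecord per S/T/Y occurrence in every sequence.

    These are the proteome-wide background sites against which
    phosphorylated-site statistics are compared.
    """
    sites: list[SiteRecord] = []
    for rec in proteome:
        for i, aa in enumerate(rec.sequence, start=1):
            if aa in VALID_RESIDUES:
                sites.append(SiteRecord(protein_id=rec.id, position=i,
                                        residue=aa, evidence="all_sty"))
    return sites


# ---------------------------------------------------------------------------
# GO annotation tables

GO_COLUMNS = ["protein_id", "term_id", "namespace"]


def read_go_table(path: str | Path) -> GOAnnotationTable:
    """Read a 3-column TSV (protein_id, term_id, namespace) of annotations."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GO table {path} missing columns {missing}")
    table = GOAnnotationTable()
    for row in df.itertuples(index=False):
        table.add(row.protein_id, row.term_id, row.namespace)
    return table


def write_go_table(table: GOAnnotationTable, path: str | Path) -> None:
    rows = [(pid, term, ns)
            for pid, terms in sorted(table.entries.items())
            for term, ns in sorted(terms)]
    pd.DataFrame(rows, columns=GO_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Homolog mapping tables

HOMOLOG_COLUMNS = ["query_protein_id", "query_position", "taxon_label",
                   "aligned_window"]


def read_homolog_table(path: str | Path) -> HomologMappingTable:
    """Read a 4-column TSV of per-taxon center-aligned homolog windows.

    Rows with a window of the wrong length are rejected and logged. If a
    (query site, taxon) pair appears more than once, the first row is kept
    and the rest are logged and dropped (best-hit selection is upstream).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in HOMOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"homolog table {path} missing columns {missing}")
    table = HomologMappingTable()
    seen: set[tuple[str, int, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.query_protein_id, int(row.query_position), row.taxon_label)
        if key in seen:
            logger.info("dropping duplicate homolog row for %s", key)
            continue
        try:
            hrow = HomologMappingRow(
                query_protein_id=row.query_protein_id,
                query_position=int(row.query_position),
                taxon_label=row.taxon_label,
                aligned_window=row.aligned_window,
            )
        except ValueError as exc:
            logger.info("rejecting homolog row: %s", exc)
            continue
        seen.add(key)
        table.rows.append(hrow)
    return table


def write_homolog_table(table: HomologMappingTable, path: str | Path) -> None:
    rows = [(r.query_protein_id, r.query_position, r.taxon_label,
             r.aligned_window) for r in table.rows]
    pd.DataFrame(rows, columns=HOMOLOG_COLUMNS).to_csv(path, sep="\t",
                                                       index=False)
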