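"""Cross-taxa conservation of methionines near phosphosites.

A phosphosite whose flanking Met recurs at the same offset in homologous
windows from distant taxa is a candidate for regulatory phosphorylation /
Met-oxidation crosstalk; a Met that is replaced by other hydrophobic
residues (Val/Ile/Leu/Phe) in most taxa more likely fills a structural role.
This module builds per-site homolog families from center-aligned 13-residue
windows, scores each query Met offset with a conservation level (number of
taxa, query included, carrying Met there), measures hydrophobic substitution
among the non-Met taxa, and classifies sites into crosstalk scenarios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections import Counter

import pandas as pd

from .io import (HomologMappingRow, HomologMappingTable, Proteome,
                 ProteinRecord, SiteRecord, WINDOW_LEN)
from .windows import SiteWindow, VILF, extract_window, window_string

logger = logging.getLogger(__name__)

HALF = WINDOW_LEN // 2  # 6

#: scenario labels, from most to least crosstalk-compatible
SCENARIOS = ("regulatory_candidate", "structural_hydrophobic",
             "site_not_conserved", "met_not_conserved", "neither_conserved")


@dataclass
class HomologFamily:
    """One query phosphosite window plus per-taxon aligned homolog windows.

    ``members`` maps taxon label -> 13-character aligned window ('-' allowed
    for gaps); the query's own taxon counts as one of the taxa.
    """

    family_id: str
    query_site: SiteRecord
    query_window: str  # 13 chars, '-' where the window runs past a terminus
    query_taxon: str
    members: dict[str, str] = field(default_factory=dict)

    @property
    def met_offsets(self) -> set[int]:
        """Offsets (-6..+6, excluding 0) where the query window holds Met."""
        return {i - HALF for i, aa in enumerate(self.query_window)
                if aa == "M" and i != HALF}

    @property
    def n_taxa(self) -> int:
        return 1 + len(self.members)

    def windows_by_taxon(self) -> dict[str, str]:
        """All aligned windows, query taxon included."""
        return {self.query_taxon: self.query_window, **self.members}


@dataclass(frozen=True)
class ConservationRecord:
    """Conservation of one query Met offset across the family's taxa.

    ``level`` counts taxa (query included) with Met at the offset;
    ``vilf_fraction`` is the fraction of the remaining taxa holding
    Val/Ile/Leu/Phe there (None when every taxon has Met).
    """

    family_id: str
    offset: int
    level: int
    n_taxa: int
    vilf_fraction: float | None


@dataclass(frozen=True)
class CrosstalkScenario:
    family_id: str
    offset: int
    scenario: str
    met_conservation_level: int
    phosphosite_conservation: float


def build_families(query_windows: list[SiteWindow], mapping: HomologMappingTable,
                   query_taxon: str = "query") -> list[HomologFamily]:
    """Assemble homolog families from query windows and a mapping table.

    Only query sites with at least one flank Met produce a family. Mapping
    rows that reference no known query site are logged and dropped; repeated
    (site, taxon) rows keep the first occurrence.
    """
    by_site: dict[tuple[str, int], HomologFamily] = {}
    for win in query_windows:
        if win.half_width != HALF:
            raise ValueError("homolog families require half-width 6 windows")
        fam = HomologFamily(
            family_id=f"{win.site.protein_id}:{win.site.position}",
            query_site=win.site,
            query_window=window_string(win),
            query_taxon=query_taxon,
        )
        if fam.met_offsets:
            by_site[(win.site.protein_id, win.site.position)] = fam
    n_orphan = 0
    for row in mapping.rows:
        key = (row.query_protein_id, row.query_position)
        fam = by_site.get(key)
        if fam is None:
            n_orphan += 1
            continue
        if row.taxon_label in fam.members or row.taxon_label == query_taxon:
            logger.info("duplicate taxon %s for family %s; keeping first",
                        row.taxon_label, fam.family_id)
            continue
        fam.members[row.taxon_label] = row.aligned_window
    if n_orphan:
        logger.info("%d mapping rows referenced non-family query sites", n_orphan)
    return [by_site[k] for k in sorted(by_site)]


def conservation_level(family: HomologFamily, offset: int) -> ConservationRecord:
    """Score Met conservation at one query Met offset.

    Gap characters count as neither Met nor VILF. ``vilf_fraction`` is over
    the taxa lacking Met at the offset and is undefined (None) at full
    conservation.
    """
    if offset not in family.met_offsets:
        raise ValueError(f"offset {offset} is not a query Met offset")
    idx = offset + HALF
    level = 0
    non_met = 0
    vilf = 0
    for window in family.windows_by_taxon().values():
        aa = window[idx]
        if aa == "M":
            level += 1
        else:
            non_met += 1
            if aa in VILF:
                vilf += 1
    frac = (vilf / non_met) if non_met else None
    return ConservationRecord(family_id=family.family_id, offset=offset,
                              level=level, n_taxa=family.n_taxa,
                              vilf_fraction=frac)


def score_families(families: list[HomologFamily]) -> list[ConservationRecord]:
    """Conservation record for every (family, query Met offset) pair."""
    return [conservation_level(fam, off)
            for fam in families for off in sorted(fam.met_offsets)]


def conservation_heatmap(records: list[ConservationRecord]) -> pd.DataFrame:
    """Proportion of scored Met positions at each conservation level.

    Returns a DataFrame with one row per observed level: the count, the
    proportion (summing to 1), and the mean VILF substitution fraction among
    records at that level (NaN where undefined for all of them).
    """
    if not records:
        return pd.DataFrame(columns=["level", "count", "proportion",
                                     "mean_vilf_fraction"])
    levels = Counter(r.level for r in records)
    total = len(records)
    rows = []
    for level in sorted(levels):
        fracs = [r.vilf_fraction for r in records
                 if r.level == level and r.vilf_fraction is not None]
        mean_vilf = sum(fracs) / len(fracs) if fracs else float("nan")
        rows.append((level, levels[level], levels[level] / total, mean_vilf))
    return pd.DataFrame(rows, columns=["level", "count", "proportion",
                                       "mean_vilf_fraction"])


def phosphosite_conservation(family: HomologFamily) -> float:
    """Fraction of taxa whose aligned center residue is S, T, or Y."""
    centers = [w[HALF] for w in family.windows_by_taxon().values()]
    return sum(c in "STY" for c in centers) / len(centers)


def classify_scenario(family: HomologFamily, offset: int,
                      high_threshold: int = 6) -> CrosstalkScenario:
    """Classify one Met-adjacent phosphosite into a crosstalk scenario.

    With the default threshold of 6-of-8 taxa: a conserved Met at a conserved
    phosphosite is a regulatory (crosstalk) candidate; a Met whose missing
    occurrences are covered by V/I/L/F substitutions is a structural
    hydrophobic placeholder; otherwise the site, the Met, or both fail
    conservation.
    """
    rec = conservation_level(family, offset)
    # phosphosite conserved when >= high_threshold of the taxa keep S/T/Y
    site_frac = phosphosite_conservation(family)
    site_conserved = site_frac * family.n_taxa >= high_threshold - 1e-9
    met_conserved = rec.level >= high_threshold
    n_vilf = round((rec.vilf_fraction or 0.0) * (family.n_taxa - rec.level))
    hydrophobic_covered = rec.level + n_vilf >= high_threshold
    if met_conserved and site_conserved:
        scenario = "regulatory_candidate"
    elif site_conserved and hydrophobic_covered:
        scenario = "structural_hydrophobic"
    elif met_conserved and not site_conserved:
        scenario = "site_not_conserved"
    elif site_conserved:
        scenario = "met_not_conserved"
    else:
        scenario = "neither_conserved"
    return CrosstalkScenario(family_id=family.family_id, offset=offset,
                             scenario=scenario,
                             met_conservation_level=rec.level,
                             phosphosite_conservation=site_frac)


def toy_homolog_matcher(query: ProteinRecord, sites: list[SiteRecord],
                        subject_proteome: Proteome, taxon_label: str,
                        min_identity: float = 0.5) -> HomologMappingTable:
    """Best-hit ungapped 13-mer matcher, a test stand-in for profile search.

    For each query site the full 13-residue window (gap-padded at termini) is
    slid over every subject sequence; identity is the fraction of the 13
    columns that match exactly. The best hit at identity >= ``min_identity``
    is returned center-aligned; ties break to the first (protein id,
    position) in sorted order. Sites take the query's site list explicitly
    since only windows around them are matched.
    """
    table = HomologMappingTable()
    subjects = sorted(subject_proteome, key=lambda r: r.id)
    for site in sites:
        if site.protein_id != query.id:
            continue
        qwin = window_string(extract_window(query, site, HALF))
        best: tuple[float, str, int, str] | None = None
        for rec in subjects:
            seq = rec.sequence
            for start in range(0, len(seq) - WINDOW_LEN + 1):
                swin = seq[start:start + WINDOW_LEN]
                ident = sum(a == b for a, b in zip(qwin, swin)) / WINDOW_LEN
                if ident < min_identity:
                    continue
                cand = (-ident, rec.id, start, swin)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            table.rows.append(HomologMappingRow(
                query_protein_id=site.protein_id,
                query_position=site.position,
                taxon_label=taxon_label,
                aligned_window=best[3],
            ))
    return table
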