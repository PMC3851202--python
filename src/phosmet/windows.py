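"""Flanking-window statistics around phosphorylatable sites.

The central object is the 13-residue window: a Ser/Thr/Tyr site plus six
residues on either side, the span that covers most known kinase-recognition
motifs. This module extracts such windows (of any half-width up to 10),
measures how often a methionine falls inside them, tabulates per-offset
residue distributions, computes proteome amino-acid composition, and scores
window hydrophobicity on the Kyte-Doolittle scale.

Amino-terminal methionine — the translation-initiator at sequence position 1
— is discounted by default: it is never counted as Met in composition,
Met-proximity, or positional distributions, since its presence reflects
translation initiation rather than motif content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import (AMBIGUOUS_AA, STANDARD_AA, Proteome, ProteinRecord,
                 SiteRecord)

#: hydrophobic residues that can structurally substitute for Met
VILF = frozenset("VILF")

DEFAULT_HALF_WIDTH = 6


def _load_scale() -> dict[str, float]:
    with resources.files("phosmet.data").joinpath("kyte_doolittle.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["residue"], df["hydropathy"]))


#: Kyte-Doolittle per-residue hydropathy values (Ile +4.5 ... Arg -4.5)
KYTE_DOOLITTLE: dict[str, float] = _load_scale()


@dataclass(frozen=True)
class SiteWindow:
    """A site plus its flanking residues at offsets -k..-1, +1..+k.

    ``flank`` maps each signed offset to a residue letter, or ``None`` where
    the offset falls beyond a sequence terminus. Offset 0 (the site itself)
    is never part of the flank.
    """

    site: SiteRecord
    half_width: int
    flank: dict[int, str | None]

    def absolute_position(self, offset: int) -> int:
        """1-based sequence position of a flank offset."""
        return self.site.position + offset

    def residues(self) -> list[tuple[int, str]]:
        """(offset, residue) pairs for non-missing slots, offset-ordered."""
        return [(d, aa) for d, aa in sorted(self.flank.items())
                if aa is not None]


def extract_window(protein: ProteinRecord, site: SiteRecord,
                   half_width: int = DEFAULT_HALF_WIDTH) -> SiteWindow:
    """Extract the +/-half_width flank around a validated site.

    Offsets outside the sequence are marked missing (``None``); truncated
    windows near termini are kept, with per-offset denominators handling the
    missing slots downstream.
    """
    if not 0 <= half_width <= 10:
        raise ValueError("half_width must be in 0..10")
    if site.protein_id != protein.id:
        raise ValueError(f"site protein {site.protein_id!r} != {protein.id!r}")
    seq = protein.sequence
    if not 1 <= site.position <= len(seq):
        raise ValueError("site position outside protein")
    if seq[site.position - 1] != site.residue:
        raise ValueError("site residue does not match sequence")
    flank: dict[int, str | None] = {}
    for d in range(-half_width, half_width + 1):
        if d == 0:
            continue
        p = site.position + d
        flank[d] = seq[p - 1] if 1 <= p <= len(seq) else None
    return SiteWindow(site=site, half_width=half_width, flank=flank)


def window_string(window: SiteWindow, gap: str = "-") -> str:
    """The window as a (2k+1)-character string, gaps at missing slots."""
    parts = []
    for d in range(-window.half_width, window.half_width + 1):
        if d == 0:
            parts.append(window.site.residue)
        else:
            aa = window.flank[d]
            parts.append(aa if aa is not None else gap)
    return "".join(parts)


def has_met(window: SiteWindow, discount_nterm: bool = True) -> bool:
    """True iff at least one flank slot holds Met.

    With ``discount_nterm`` (the default), a Met whose absolute sequence
    position is 1 — the translation initiator — is ignored.
    """
    for d, aa in window.flank.items():
        if aa != "M":
            continue
        if discount_nterm and window.absolute_position(d) == 1:
            continue
        return True
    return False


@dataclass(frozen=True)
class MetProximityResult:
    """Proportion of sites in one (residue, evidence) group with flank Met."""

    residue_type: str
    group: str
    n_sites: int
    n_with_met: int

    @property
    def proportion(self) -> float:
        """Percentage of sites with at least one (counted) flank Met."""
        return 100.0 * self.n_with_met / self.n_sites


def met_proximity_table(proteome: Proteome, sites: list[SiteRecord],
                        half_width: int = DEFAULT_HALF_WIDTH,
                        discount_nterm: bool = True,
                        ) -> list[MetProximityResult]:
    """Met-proximity proportions per (residue type x evidence group).

    Groups with zero sites are omitted. Sites are assumed validated.
    """
    counts: dict[tuple[str, str], list[int]] = {}
    for site in sites:
        win = extract_window(proteome[site.protein_id], site, half_width)
        key = (site.residue, site.evidence)
        c = counts.setdefault(key, [0, 0])
        c[0] += 1
        if has_met(win, discount_nterm=discount_nterm):
            c[1] += 1
    return [MetProximityResult(residue_type=r, group=g, n_sites=c[0],
                               n_with_met=c[1])
            for (r, g), c in sorted(counts.items())]


@dataclass
class PositionalDistribution:
    """Per-offset occurrence percentages of a residue class around sites.

    ``percentages[d]`` = 100 x (sites with a class residue at offset d) /
    (sites with a non-missing slot at d); ``None`` where the denominator is
    zero. Counts and denominators are kept for downstream chi-square tests.
    """

    residue_class: str
    counts: dict[int, int]
    denominators: dict[int, int]

    @property
    def percentages(self) -> dict[int, float | None]:
        return {d: (100.0 * self.counts[d] / n if n else None)
                for d, n in self.denominators.items()}


def _class_members(residue_class: str) -> frozenset[str]:
    if residue_class == "VILF":
        return VILF
    if len(residue_class) == 1 and residue_class in STANDARD_AA:
        return frozenset(residue_class)
    raise ValueError(f"unknown residue class {residue_class!r}")


def positional_distribution(proteome: Proteome, sites: list[SiteRecord],
                            residue_class: str = "M",
                            half_width: int = DEFAULT_HALF_WIDTH,
                            discount_nterm: bool = True,
                            ) -> PositionalDistribution:
    """Per-offset distribution of a residue class in site flanks.

    ``residue_class`` is a single residue letter (typically ``M``) or the
    pooled hydrophobic class ``VILF``. When the class includes Met, the
    amino-terminal Met is not counted (it stays in the denominator: the slot
    exists, it just never counts as Met).
    """
    members = _class_members(residue_class)
    counts = {d: 0 for d in range(-half_width, half_width + 1) if d != 0}
    denoms = {d: 0 for d in counts}
    for site in sites:
        win = extract_window(proteome[site.protein_id], site, half_width)
        for d, aa in win.flank.items():
            if aa is None:
                continue
            denoms[d] += 1
            if aa in members:
                if (aa == "M" and discount_nterm
                        and win.absolute_position(d) == 1):
                    continue
                counts[d] += 1
    return PositionalDistribution(residue_class=residue_class, counts=counts,
                                  denominators=denoms)


@dataclass
class CompositionTable:
    """Per-residue proportions (%) over a proteome's standard residues."""

    proportions: dict[str, float]
    n_counted: int

    def __getitem__(self, residue: str) -> float:
        return self.proportions[residue]


def composition(proteome: Proteome,
                discount_nterm: bool = True) -> CompositionTable:
    """Amino-acid composition (%) over the 20 standard residues.

    With ``discount_nterm``, an initiator Met at position 1 is excluded from
    both numerator and denominator. Ambiguity letters are never counted.
    """
    counts = {aa: 0 for aa in STANDARD_AA}
    for rec in proteome:
        seq = rec.sequence
        start = 0
        if discount_nterm and seq[0] == "M":
            start = 1
        for aa in seq[start:]:
            if aa in counts:
                counts[aa] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("proteome has no standard residues to count")
    return CompositionTable(
        proportions={aa: 100.0 * c / total for aa, c in counts.items()},
        n_counted=total,
    )


def hydropathy_score(window: SiteWindow) -> float | None:
    """Mean Kyte-Doolittle hydropathy over the flank.

    The site residue itself is excluded (the flank never contains it);
    missing slots and ambiguity letters contribute nothing. Returns ``None``
    when no scorable residue exists, signalling an undefined score.
    """
    values = [KYTE_DOOLITTLE[aa] for _, aa in window.residues()
              if aa not in AMBIGUOUS_AA]
    if not values:
        return None
    return math.fsum(values) / len(values)


def hydropathy_table(proteome: Proteome, sites: list[SiteRecord],
                     half_width: int = DEFAULT_HALF_WIDTH) -> pd.DataFrame:
    """Per-site hydropathy scores as a tidy DataFrame."""
    rows = []
    for site in sites:
        win = extract_window(proteome[site.protein_id], site, half_width)
        rows.append((site.protein_id, site.position, site.residue,
                     site.evidence, hydropathy_score(win)))
    return pd.DataFrame(rows, columns=["protein_id", "position", "residue",
                                       "evidence", "hydropathy"])


def window_size_scan(proteome: Proteome, sites: list[SiteRecord],
                     half_widths: range | list[int] = range(1, 11),
                     discount_nterm: bool = True) -> pd.DataFrame:
    """Met-proximity proportions across window half-widths 1..10.

    For fixed sites the proportion is non-decreasing in half-width, since a
    wider window contains every narrower one.
    """
    rows = []
    for k in half_widths:
        for res in met_proximity_table(proteome, sites, half_width=k,
                                       discount_nterm=discount_nterm):
            rows.append((k, 2 * k + 1, res.residue_type, res.group,
                         res.n_sites, res.n_with_met, res.proportion))
    return pd.DataFrame(rows, columns=["half_width", "window_length",
                                       "residue", "evidence", "n_sites",
                                       "n_with_met", "proportion_pct"])
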