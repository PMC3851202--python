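"""Synthetic proteomes with planted, recoverable statistical structure.

Every pipeline stage is testable without downloads: this module generates
(1) proteomes with a configurable amino-acid composition (Met ~2.4% by
default, every sequence starting with the initiator Met), (2) phosphosite
tables whose windows are edited so the fraction containing a Met is an exact
Bernoulli draw at a target probability, (3) per-site homolog families whose
Met-conservation levels follow a chosen distribution, and (4) GO annotation
tables with terms enriched by a known fold in a designated subpopulation.

Each generator parameter is recoverable by the corresponding analysis stage
to within sampling error — that recoverability is what the test suite
exercises. Everything is deterministic given the config seed; each generator
draws from its own seed stream so outputs do not depend on call order.

The default residue composition is a synthetic, qualitatively
eukaryote-like table (Ser high; Met, Cys, His, Trp, Tyr low) shipped as a
versioned data file; it mirrors no specific organism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import (GOAnnotationTable, HomologMappingRow, HomologMappingTable,
                 Proteome, ProteinRecord, SiteRecord)
from .windows import VILF, extract_window, has_met, window_string

logger = logging.getLogger(__name__)

HALF = 6  # homolog windows are 13-mers


def default_composition() -> dict[str, float]:
    """The packaged synthetic eukaryote-like residue frequency table."""
    path = resources.files("phosmet.data").joinpath("default_composition.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["residue"], df["fraction"]))


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic generators; ``seed`` is mandatory.

    Defaults give a mid-sized proteome (300 proteins, mean length 450) with
    1000 planted phosphosites at the 14% Met-in-window probability seen for
    phosphorylated sites, a uniform Met-conservation level distribution over
    1..8 taxa, and one GO term planted at 3-fold enrichment.
    """

    seed: int
    n_proteins: int = 300
    length_mean: float = 450.0
    length_dispersion: float = 3.0  # gamma shape; smaller = broader spread
    min_length: int = 30
    composition: dict[str, float] = field(default_factory=default_composition)
    n_phosphosites: int = 1000
    p_met_in_window: float = 0.14
    predicted_fraction: float = 0.0
    half_width: int = HALF
    n_taxa: int = 8
    conservation_level_distribution: dict[int, float] = field(
        default_factory=lambda: {lv: 1 / 8 for lv in range(1, 9)})
    vilf_substitution_fraction: float = 0.5
    center_conservation: float = 1.0
    n_go_terms: int = 30
    go_background_freq: float = 0.10
    planted_terms: dict[str, float] = field(
        default_factory=lambda: {"GO:1000001": 3.0})
    taxon_label: str = "synthetic"

    def __post_init__(self):
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"composition sums to {total}, expected 1")
        if not 0 <= self.p_met_in_window <= 1:
            raise ValueError("p_met_in_window must be in [0, 1]")
        for lv, p in self.conservation_level_distribution.items():
            if p < 0 or (p > 0 and not 1 <= lv <= self.n_taxa):
                raise ValueError(f"bad conservation level {lv} (p={p})")
        for term, fold in self.planted_terms.items():
            if fold < 1:
                raise ValueError(f"fold factor for {term} must be >= 1")

    def rng(self, salt: int) -> np.random.Generator:
        """A generator-specific stream: independent of call order."""
        return np.random.default_rng([self.seed, salt])


def generate_proteome(config: SyntheticConfig) -> Proteome:
    """Sequences i.i.d. from the configured composition, initiator Met first.

    Lengths are gamma-distributed (shape = dispersion) around the mean with
    a floor, emulating the long right tail of real protein-length
    distributions.
    """
    rng = config.rng(1)
    letters = np.array(sorted(config.composition))
    probs = np.array([config.composition[aa] for aa in letters])
    probs = probs / probs.sum()
    if config.length_dispersion > 0:
        lengths = np.maximum(
            config.min_length,
            rng.gamma(config.length_dispersion,
                      config.length_mean / config.length_dispersion,
                      size=config.n_proteins).astype(int),
        )
    else:  # dispersion 0: constant length
        lengths = np.full(config.n_proteins, int(config.length_mean))
    records = []
    for i, L in enumerate(lengths):
        body = rng.choice(letters, size=int(L) - 1, p=probs)
        records.append(ProteinRecord(id=f"syn{i:05d}",
                                     sequence="M" + "".join(body)))
    return Proteome(records=records, taxon_label=config.taxon_label)


def plant_phosphosites(proteome: Proteome, config: SyntheticConfig,
                       ) -> tuple[Proteome, list[SiteRecord]]:
    """Plant phosphosites with an exact Bernoulli Met-in-window probability.

    S/T/Y positions are sampled in random order and accepted greedily only
    if their window is disjoint from every previously accepted window, so
    edits never collide and sites' Met statuses are independent. Each
    accepted site's window is then edited: with probability
    ``p_met_in_window`` a Met is written into a random flank position (if
    none is there already); otherwise every counting flank Met is replaced
    by a composition-weighted non-Met residue. Edits never touch accepted
    site centers or the initiator position. Returns the edited proteome and
    the site table.
    """
    rng = config.rng(2)
    k = config.half_width
    seqs = {rec.id: list(rec.sequence) for rec in proteome}
    candidates = [(rec.id, i + 1)
                  for rec in proteome
                  for i, aa in enumerate(rec.sequence) if aa in "STY"]
    if len(candidates) < config.n_phosphosites:
        raise ValueError(
            f"only {len(candidates)} S/T/Y positions for "
            f"{config.n_phosphosites} requested sites")
    order = rng.permutation(len(candidates))
    occupied: dict[str, set[int]] = {rec.id: set() for rec in proteome}
    chosen: list[tuple[str, int]] = []
    n_skipped = 0
    for idx in order:
        pid, pos = candidates[idx]
        span = set(range(pos - k, pos + k + 1))
        if span & occupied[pid]:
            n_skipped += 1
            continue
        occupied[pid] |= span
        chosen.append((pid, pos))
        if len(chosen) == config.n_phosphosites:
            break
    if len(chosen) < config.n_phosphosites:
        raise ValueError("could not place requested sites without window overlap")
    if n_skipped:
        logger.info("skipped %d candidate sites with overlapping windows",
                    n_skipped)

    centers = set(chosen)
    letters = np.array(sorted(config.composition))
    probs = np.array([config.composition[aa] for aa in letters])
    non_met = letters != "M"
    non_met_probs = probs[non_met] / probs[non_met].sum()
    non_met_letters = letters[non_met]

    chosen.sort()
    sites: list[SiteRecord] = []
    for pid, pos in chosen:
        seq = seqs[pid]
        length = len(seq)
        flank_positions = [pos + d for d in range(-k, k + 1)
                           if d != 0 and 1 <= pos + d <= length]
        # a Met at position 1 is the discounted initiator; it never counts
        met_positions = [p for p in flank_positions
                         if seq[p - 1] == "M" and p != 1]
        want_met = rng.random() < config.p_met_in_window
        if want_met and not met_positions:
            editable = [p for p in flank_positions
                        if p != 1 and (pid, p) not in centers]
            if not editable:
                logger.info("no editable flank for %s:%d; dropping site",
                            pid, pos)
                continue
            target = editable[rng.integers(len(editable))]
            seq[target - 1] = "M"
        elif not want_met and met_positions:
            for p in met_positions:
                seq[p - 1] = str(rng.choice(non_met_letters, p=non_met_probs))
        evidence = ("predicted"
                    if rng.random() < config.predicted_fraction
                    else "experimental")
        sites.append(SiteRecord(protein_id=pid, position=pos,
                                residue=seq[pos - 1], evidence=evidence))
    edited = Proteome(
        records=[ProteinRecord(id=rec.id, sequence="".join(seqs[rec.id]))
                 for rec in proteome],
        taxon_label=proteome.taxon_label,
        kingdom_group=proteome.kingdom_group,
    )
    return edited, sites


def generate_homolog_families(proteome: Proteome, sites: list[SiteRecord],
                              config: SyntheticConfig) -> HomologMappingTable:
    """Per-taxon aligned windows with planted Met-conservation levels.

    For every site whose window holds a counting Met, ``n_taxa - 1`` member
    windows are emitted (taxa ``taxon1..``). At each query Met offset a
    level L is drawn from the configured distribution; L - 1 randomly chosen
    members carry Met there, and each remaining member carries V/I/L/F with
    the configured substitution probability (otherwise a composition-drawn
    residue that is neither Met nor V/I/L/F). Member centers keep S/T/Y with
    probability ``center_conservation``. All other columns copy the query.
    """
    rng = config.rng(3)
    n_members = config.n_taxa - 1
    levels = sorted(lv for lv, p in
                    config.conservation_level_distribution.items() if p > 0)
    level_probs = np.array([config.conservation_level_distribution[lv]
                            for lv in levels], dtype=float)
    level_probs = level_probs / level_probs.sum()

    letters = np.array(sorted(config.composition))
    probs = np.array([config.composition[aa] for aa in letters])
    neutral = np.array([aa not in VILF and aa != "M" for aa in letters])
    neutral_probs = probs[neutral] / probs[neutral].sum()
    neutral_letters = letters[neutral]
    vilf_letters = np.array(sorted(VILF))
    non_sty = np.array([aa not in "STY" for aa in letters])
    non_sty_probs = probs[non_sty] / probs[non_sty].sum()
    non_sty_letters = letters[non_sty]

    table = HomologMappingTable()
    for site in sorted(sites, key=lambda s: (s.protein_id, s.position)):
        win = extract_window(proteome[site.protein_id], site, HALF)
        if not has_met(win, discount_nterm=False):
            continue
        qstr = window_string(win)
        met_cols = [i for i, aa in enumerate(qstr) if aa == "M" and i != HALF]
        members = [list(qstr) for _ in range(n_members)]
        for col in met_cols:
            level = int(np.asarray(levels)[rng.choice(len(levels),
                                                      p=level_probs)])
            with_met = rng.choice(n_members, size=level - 1, replace=False)
            met_set = set(int(j) for j in with_met)
            for j in range(n_members):
                if j in met_set:
                    members[j][col] = "M"
                elif rng.random() < config.vilf_substitution_fraction:
                    members[j][col] = str(vilf_letters[rng.integers(4)])
                else:
                    members[j][col] = str(rng.choice(neutral_letters,
                                                     p=neutral_probs))
        for j in range(n_members):
            if rng.random() >= config.center_conservation:
                members[j][HALF] = str(rng.choice(non_sty_letters,
                                                  p=non_sty_probs))
            table.rows.append(HomologMappingRow(
                query_protein_id=site.protein_id,
                query_position=site.position,
                taxon_label=f"taxon{j + 1}",
                aligned_window="".join(members[j]),
            ))
    return table


def generate_go_annotations(proteome: Proteome, config: SyntheticConfig,
                            test_proteins: set[str] | None = None,
                            ) -> GOAnnotationTable:
    """Coin-flip GO annotations with fold-enriched planted terms.

    Background terms ``GO:0000001..`` are assigned independently at the
    configured frequency; planted terms are assigned at frequency x fold for
    proteins in ``test_proteins`` (the designated enriched subpopulation)
    and at the base frequency elsewhere. Namespaces cycle BP/MF/CC.
    """
    rng = config.rng(4)
    test_proteins = test_proteins or set()
    namespaces = ("BP", "MF", "CC")
    terms = [(f"GO:{i + 1:07d}", namespaces[i % 3], config.go_background_freq,
              1.0) for i in range(config.n_go_terms)]
    for j, (term, fold) in enumerate(sorted(config.planted_terms.items())):
        terms.append((term, namespaces[j % 3], config.go_background_freq,
                      fold))
    table = GOAnnotationTable()
    for rec in sorted(proteome, key=lambda r: r.id):
        in_test = rec.id in test_proteins
        for term, ns, freq, fold in terms:
            p = min(1.0, freq * (fold if in_test else 1.0))
            if rng.random() < p:
                table.add(rec.id, term, ns)
    return table
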