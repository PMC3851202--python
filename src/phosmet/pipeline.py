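"""End-to-end orchestration: inputs (read or simulated) -> report bundle.

``run_all`` drives every stage in order — composition, Met-proximity with
two-proportion Z-tests against the proteome-wide S/T/Y background,
positional distributions with a chi-square test of offset independence,
hydropathy scores, the window-size scan, cross-taxa conservation with
crosstalk-scenario classification, and GO enrichment at each conservation
threshold — writing one TSV per stage plus a machine-readable JSON manifest
(config, seed, row counts). Any stage failure aborts the run with the stage
named and removes the partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from . import simulate as sim
from .conservation import (build_families, classify_scenario,
                           conservation_heatmap, score_families)
from .enrichment import define_sets, enrichment_frame, run_enrichment
from .stats import chi_square_independence, two_proportion_z
from .windows import (composition, extract_window, hydropathy_table,
                      met_proximity_table, positional_distribution,
                      window_size_scan)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for a full pipeline run.

    Provide either the four input paths (FASTA proteome, site TSV, GO TSV,
    homolog TSV) or a :class:`~phosmet.simulate.SyntheticConfig`; the
    synthetic route generates all four in memory.
    """

    out_dir: str | Path
    seed: int = 0
    fasta_path: str | Path | None = None
    sites_path: str | Path | None = None
    go_path: str | Path | None = None
    homolog_path: str | Path | None = None
    synthetic: sim.SyntheticConfig | None = None
    half_width: int = 6
    discount_nterm: bool = True
    alpha: float = 0.05
    high_threshold: int = 6
    conservation_panels: tuple[int, ...] = (7, 6, 5, 4)

    def __post_init__(self):
        if not 0 <= self.half_width <= 10:
            raise ValueError("half_width must be in 0..10")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.synthetic is None and (self.fasta_path is None
                                       or self.sites_path is None):
            raise ValueError("need input paths or a synthetic config")


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        proteome = sim.generate_proteome(syn)
        proteome, sites = sim.plant_phosphosites(proteome, syn)
        homologs = sim.generate_homolog_families(proteome, sites, syn)
        test, _ = define_sets(sites, proteome, config.half_width,
                              config.discount_nterm)
        annotations = sim.generate_go_annotations(proteome, syn,
                                                  test_proteins=test)
        return proteome, sites, annotations, homologs
    proteome = pio.read_fasta(config.fasta_path)
    sites = pio.read_site_table(config.sites_path, proteome)
    annotations = (pio.read_go_table(config.go_path)
                   if config.go_path else pio.GOAnnotationTable())
    homologs = (pio.read_homolog_table(config.homolog_path)
                if config.homolog_path else pio.HomologMappingTable())
    return proteome, sites, annotations, homologs


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run every stage; return {table name: written path}.

    Tables are the canonical outputs; the manifest records config, seed and
    per-table row counts so any table can be reproduced from it.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    row_counts: dict[str, int] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
        row_counts[name] = len(df)

    stage = "load_inputs"
    try:
        proteome, sites, annotations, homologs = _load_inputs(config)
        background_sites = pio.enumerate_all_sty(proteome)
        all_sites = sites + background_sites

        stage = "composition"
        comp = composition(proteome, discount_nterm=config.discount_nterm)
        emit("composition", pd.DataFrame(
            sorted(comp.proportions.items()),
            columns=["residue", "percent"]))

        stage = "proximity"
        prox = met_proximity_table(proteome, all_sites, config.half_width,
                                   config.discount_nterm)
        by_key = {(r.residue_type, r.group): r for r in prox}
        rows = []
        for r in prox:
            bg = by_key.get((r.residue_type, "all_sty"))
            if r.group != "all_sty" and bg is not None:
                cmpres = two_proportion_z(r.n_with_met, r.n_sites,
                                          bg.n_with_met, bg.n_sites)
                z, p = cmpres.z, cmpres.p_two_sided
            else:
                z, p = float("nan"), float("nan")
            rows.append((r.residue_type, r.group, r.n_sites, r.n_with_met,
                         r.proportion, z, p))
        emit("proximity", pd.DataFrame(
            rows, columns=["residue", "evidence", "n_sites", "n_with_met",
                           "proportion_pct", "z_vs_all_sty", "p_vs_all_sty"]))

        stage = "positions"
        rows = []
        chi_rows = []
        for label, group_sites in (("phospho", sites),
                                   ("all_sty", background_sites)):
            if not group_sites:
                continue
            for residue_class in ("M", "VILF"):
                dist = positional_distribution(
                    proteome, group_sites, residue_class, config.half_width,
                    config.discount_nterm)
                for d in sorted(dist.counts):
                    rows.append((label, residue_class, d, dist.counts[d],
                                 dist.denominators[d],
                                 dist.percentages[d]))
                table = [[dist.counts[d] for d in sorted(dist.counts)
                          if dist.denominators[d]],
                         [dist.denominators[d] - dist.counts[d]
                          for d in sorted(dist.counts)
                          if dist.denominators[d]]]
                if len(table[0]) >= 2 and sum(table[0]) and sum(table[1]):
                    chi = chi_square_independence(table)
                    chi_rows.append((label, residue_class, chi.statistic,
                                     chi.dof, chi.p))
        emit("positions", pd.DataFrame(
            rows, columns=["site_group", "residue_class", "offset", "count",
                           "denominator", "percent"]))
        emit("positions_chi2", pd.DataFrame(
            chi_rows, columns=["site_group", "residue_class", "statistic",
                               "dof", "p"]))

        stage = "hydropathy"
        emit("hydropathy", hydropathy_table(proteome, sites,
                                            config.half_width))

        stage = "scan"
        emit("scan", window_size_scan(proteome, sites,
                                      discount_nterm=config.discount_nterm))

        stage = "conservation"
        windows = [extract_window(proteome[s.protein_id], s, 6)
                   for s in sites]
        families = build_families(windows, homologs,
                                  query_taxon=proteome.taxon_label)
        records = score_families(families)
        emit("conservation", pd.DataFrame(
            [(r.family_id, r.offset, r.level, r.n_taxa,
              r.vilf_fraction if r.vilf_fraction is not None else float("nan"))
             for r in records],
            columns=["family_id", "offset", "level", "n_taxa",
                     "vilf_fraction"]))
        emit("conservation_heatmap", conservation_heatmap(records))
        scen = [classify_scenario(f, off, config.high_threshold)
                for f in families for off in sorted(f.met_offsets)]
        emit("scenarios", pd.DataFrame(
            [(s.family_id, s.offset, s.scenario, s.met_conservation_level,
              s.phosphosite_conservation) for s in scen],
            columns=["family_id", "offset", "scenario",
                     "met_conservation_level", "phosphosite_conservation"]))

        stage = "enrichment"
        test, background = define_sets(sites, proteome, config.half_width,
                                       config.discount_nterm)
        emit("enrichment_any_met", enrichment_frame(
            run_enrichment(test, background, annotations, config.alpha)))
        for level in config.conservation_panels:
            test_l, bg = define_sets(sites, proteome, config.half_width,
                                     config.discount_nterm,
                                     families=families,
                                     min_conservation=level)
            emit(f"enrichment_conserved_ge{level}", enrichment_frame(
                run_enrichment(test_l, bg, annotations, config.alpha)))

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "half_width": config.half_width,
            "discount_nterm": config.discount_nterm,
            "alpha": config.alpha,
            "high_threshold": config.high_threshold,
            "conservation_panels": list(config.conservation_panels),
            "synthetic": (dataclasses.asdict(config.synthetic)
                          if config.synthetic else None),
            "inputs": {k: str(getattr(config, k)) for k in
                       ("fasta_path", "sites_path", "go_path",
                        "homolog_path") if getattr(config, k)},
            "n_proteins": len(proteome),
            "n_sites": len(sites),
            "n_background_sites": len(background_sites),
            "row_counts": row_counts,
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2,
                                            sort_keys=True) + "\n")
        written["manifest"] = manifest_path
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline complete: %d tables in %s", len(written), out_dir)
    return written
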