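# Methods

## Window model

A site's context is the flank at signed offsets −k…−1, +1…+k around its
1-based sequence position; the default half-width is k = 6, a 13-residue
window wide enough to cover most kinase-recognition motifs while staying
position-specific. Offset 0 (the site itself) is never part of the flank.
Sites closer than k to a terminus are **included** with truncated windows:
out-of-range offsets are marked missing, and every per-offset statistic uses
a per-offset denominator (the number of sites whose position + d lies inside
the protein), so truncation biases nothing. "Met proximity" means *at least
one* Met among the non-missing flank slots.

**Amino-terminal discounting.** The residue at sequence position 1 is the
translation initiator and is Met in essentially every translated protein, so
it is never counted as Met — in composition (where it is dropped from both
numerator and denominator), in Met-proximity, and in positional
distributions (where the slot stays in the denominator; it simply never
counts as a Met occurrence). The flag `discount_nterm` (default on) applies
the rule uniformly.

**Hydropathy.** A window's score is the arithmetic **mean** of
Kyte–Doolittle values over non-missing, non-ambiguous flank residues, the
site excluded. The mean (rather than the sum) keeps truncated windows
comparable to full ones; because the aggregation choice is a package
convention, hydropathy values should be used comparatively, not as absolute
scores. The value table ships as a versioned data file
(`data/kyte_doolittle.tsv`) so scores are bit-reproducible. Ambiguity
letters B/Z/X/U are retained in sequences but never counted as Met or
hydrophobic and contribute nothing to hydropathy averaging.

## Statistical procedures

- **Two-proportion Z-test** — pooled-variance form (the standard choice
  under the null of equal proportions), two-sided p from the normal. A
  degenerate pooled proportion (0 or 1) carries no evidence of difference:
  z := 0, p := 1.
- **χ² test of independence** — Pearson statistic with margin-derived
  expected counts, no Yates correction by default (per-offset counts in
  this analysis are large); a flag enables it for small 2×2 tables.
- **Hypergeometric enrichment** — one-sided upper tail P[X ≥ k], summed
  term-by-term in log space (log-gamma binomials) for numerical stability;
  enrichment only, depletion is not tested. Tests agree with exact rational
  enumeration for every universe N ≤ 25.
- **Bonferroni** — adjusted p = min(1, m·p) with m = the number of terms
  with at least one test-set annotation (the convention of the common GO
  webservers); m may be set to the full annotated-term count instead.
- **log₂ enrichment ratio** — log₂ of the test/background proportion ratio,
  defined only when the term occurs in both sets; 0.5 ⇔ a 41% increase.
- **PTM combinatorics** — (t+1)ⁿ molecular species for n sites and t
  modification types per site.

Enrichment terms from all three GO namespaces form a single Bonferroni
family, and annotations are used exactly as given — no ancestor roll-up
through the GO graph. Supply pre-propagated tables when roll-up semantics
are wanted; results are order-independent in the annotation rows.

## Conservation scoring

Homolog context arrives as a consumed table of per-taxon center-aligned
13-mers (one row per query site × taxon; profile search itself is out of
scope — a toy exact-13-mer matcher is provided for tests only). The
conservation level of a query Met offset counts the taxa — **query
included** — whose aligned window carries M there; with 7 member taxa the
level ranges 1–8. Gaps count as neither Met nor V/I/L/F. Among taxa lacking
Met at the offset, the V/I/L/F fraction measures hydrophobic substitution;
it is undefined at full conservation.

Scenario classification with high-threshold H (default 6 of 8; panels at
≥7, ≥6, ≥5, ≥4 are exposed in the pipeline config): *regulatory candidate*
when level ≥ H and ≥ H taxa keep an S/T/Y center; *structural hydrophobic*
when the center is conserved and level + V/I/L/F substitutions ≥ H;
otherwise the classification names the failing element (site, Met, or
both).

## Synthetic data

The generators emulate the statistical structure the analyses measure, not
biology: sequences are i.i.d. draws from a configurable composition
(default: a synthetic eukaryote-like table with Met 2.4%, Ser 8.1%; shipped
as `data/default_composition.tsv`), lengths gamma-distributed (shape 3,
mean 450, floor 30 — a realistic right-skewed protein-length spread;
dispersion 0 gives constant lengths), and every sequence starts with the
initiator Met.

Phosphosites are planted by sampling S/T/Y positions in random order and
accepting greedily only those whose windows are pairwise disjoint
(collisions are logged and skipped), so per-site window edits never
interact. Each accepted site's Met status is then set by an independent
Bernoulli(p_met_in_window) draw — planting a Met at a random editable flank
position or erasing the counting flank Mets — making the number of
Met-containing windows exactly Binomial(n, p). Edits never touch accepted
site centers or position 1. Defaults: 1000 sites at p = 0.14, the
phosphosite-vs-background gap the analyses are built to detect.

Homolog families plant a conservation level **per query Met offset**, drawn
from a configurable distribution (default uniform over 1…8): level − 1 of
the 7 member windows get Met there, the rest get V/I/L/F with the
substitution fraction (default 0.5) or a neutral residue; all other columns
copy the query, and member centers stay S/T/Y with probability
`center_conservation` (default 1). GO annotations are independent coin
flips at a background frequency (default 0.1 over 30 terms) with planted
terms boosted by a fold factor (default one term at 3×) inside a designated
subpopulation.

What the generators do **not** emulate: kinase-motif grammars, positional
composition biases, homology by descent (no substitution models or trees),
or the GO term dependency structure. Passing recovery tests therefore shows
the estimators are unbiased and correctly calibrated on known structure —
not that real proteomes satisfy the i.i.d. assumptions.

Determinism: every generator draws from `default_rng([seed, salt])` with a
per-generator salt, so outputs are identical for a given config seed
regardless of call order, and the full pipeline is byte-reproducible.

## Numerical and design notes

- Positions are 1-based in all external tables; offsets are signed with 0 at
  the site. Site tables are 4-column TSV with a header; homolog tables
  4-column TSV; GO tables 3-column TSV.
- The proteome-wide S/T/Y background **includes** the phosphorylated sites
  (a superset background); exclusion is a caller-side filter.
- The toy matcher breaks equal-identity ties to the first (protein id,
  position) in sorted order.
- Hypergeometric inputs are validated (k ≤ min(K, n) ≤ N); a violated
  invariant raises rather than returning a clipped value.
- `run_all` aborts on the first failing stage, names it, and removes the
  partial outputs; the manifest (config, seed, row counts) suffices to
  reproduce any table.

## Problem sizes

Recovery checks run at the sizes where their tolerances are meaningful:
5000 planted sites for the 14% ± 1.5 Met-in-window recovery (±3 binomial
SD ≈ 1.5 points), ~8000 scored Met offsets for the uniform-level recovery
(±3 multinomial SD ≈ 0.011 per level), 100 replicates for planted GO-term
recovery, and 1000 null replicates for family-wise error control
(0.05 + 3·SE ≈ 0.071 bound). The default test suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

- No FDR-style correction (Bonferroni only), no permutation tests.
- No GO-graph propagation or term-name resolution; term ids pass through.
- Hydropathy aggregation (mean) is a convention; absolute values are not
  comparable to sum-based pipelines.
- Isoforms are treated as independent proteins; collapsing splice variants
  is upstream of this package.
- The window-overlap skip rule in the site planter means very dense site
  requests on small proteomes fail loudly rather than planting correlated
  sites.
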