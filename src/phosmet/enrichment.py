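"""Local GO term over-representation analysis.

Test set: phosphoproteins carrying at least one phosphosite with a Met in
the flanking window (optionally restricted to sites whose Met reaches a
given cross-taxa conservation level). Background: all phosphoproteins. Each
term annotated in the test set gets a one-sided hypergeometric p-value,
Bonferroni correction over the number of terms tested, a companion
two-proportion z-score, and the log2 test-vs-background enrichment ratio.

Annotations are used as given — no GO-graph ancestor propagation; supply
pre-propagated tables if roll-up is wanted. Terms from all three namespaces
are corrected jointly (a single Bonferroni family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .conservation import HomologFamily, score_families
from .io import GOAnnotationTable, Proteome, SiteRecord
from .stats import (bonferroni, enrichment_z, hypergeometric_upper,
                    log2_enrichment_ratio)
from .windows import extract_window, has_met

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One GO term's enrichment evidence in the test set vs background."""

    term_id: str
    namespace: str
    k: int  # test-set proteins with term
    n: int  # test-set size
    K: int  # background proteins with term
    N: int  # background size
    p_raw: float
    p_bonferroni: float
    z: float
    log2_ratio: float
    significant: bool


def define_sets(sites: list[SiteRecord], proteome: Proteome,
                half_width: int = 6, discount_nterm: bool = True,
                families: list[HomologFamily] | None = None,
                min_conservation: int | None = None,
                ) -> tuple[set[str], set[str]]:
    """Build (test, background) protein sets for enrichment.

    Background = every protein with a phosphosite in ``sites``. Test = the
    subset with at least one Met-in-window site; with ``min_conservation``
    set, only sites whose Met offset reaches that conservation level (scored
    from ``families``) qualify. Proteins are deduplicated: many qualifying
    sites still count once.
    """
    background = {s.protein_id for s in sites}
    if not background:
        raise ValueError("empty background: no phosphoproteins")
    if min_conservation is not None:
        if families is None:
            raise ValueError("min_conservation filter requires families")
        qualifying = {
            rec.family_id.rsplit(":", 1)[0]
            for rec in score_families(families)
            if rec.level >= min_conservation
        }
        test = qualifying & background
        if not test:
            logger.warning("no proteins reach conservation level >= %d",
                           min_conservation)
    else:
        test = set()
        for site in sites:
            win = extract_window(proteome[site.protein_id], site, half_width)
            if has_met(win, discount_nterm=discount_nterm):
                test.add(site.protein_id)
    return test, background


def run_enrichment(test: set[str], background: set[str],
                   annotations: GOAnnotationTable, alpha: float = 0.05,
                   ) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test for every test-set term.

    Bonferroni m = number of terms with at least one test-set annotation
    (the convention of the agriGO/g:Profiler-style services). Results are
    sorted by adjusted p then term id.
    """
    if not test <= background:
        raise ValueError("test set must be a subset of the background")
    N, n = len(background), len(test)
    term_ns: dict[str, str] = {}
    k_counts: dict[str, int] = {}
    K_counts: dict[str, int] = {}
    for pid in background:
        for term, ns in annotations.terms_of(pid):
            term_ns[term] = ns
            K_counts[term] = K_counts.get(term, 0) + 1
            if pid in test:
                k_counts[term] = k_counts.get(term, 0) + 1
    tested = sorted(k_counts)
    m = len(tested)
    p_raw = [hypergeometric_upper(k_counts[t], K_counts[t], n, N)
             for t in tested]
    p_adj = bonferroni(p_raw, m=m) if tested else []
    results = []
    for term, praw, padj in zip(tested, p_raw, p_adj):
        k, K = k_counts[term], K_counts[term]
        results.append(EnrichmentResult(
            term_id=term, namespace=term_ns[term], k=k, n=n, K=K, N=N,
            p_raw=praw, p_bonferroni=padj,
            z=enrichment_z(k, K, n, N),
            log2_ratio=log2_enrichment_ratio(k, n, K, N),
            significant=padj < alpha,
        ))
    results.sort(key=lambda r: (r.p_bonferroni, r.term_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """EnrichmentResults as a bar-plot-ready tidy DataFrame."""
    return pd.DataFrame(
        [(r.term_id, r.namespace, r.k, r.n, r.K, r.N, r.p_raw,
          r.p_bonferroni, r.z, r.log2_ratio, r.significant)
         for r in results],
        columns=["term_id", "namespace", "k", "n", "K", "N", "p_raw",
                 "p_bonferroni", "z", "log2_ratio", "significant"],
    )
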