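"""Hypergeometric term enrichment with Bonferroni correction and rich factors.

With N annotated background genes, n of them differentially expressed, M
genes carrying a given term and m of those differentially expressed, the
enrichment p-value is the upper hypergeometric tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)  =  P(X >= m).

Bonferroni multiplies by the number of terms tested and clamps at 1. The
*rich factor* m/M — the fraction of a term's genes that are differentially
expressed — summarizes effect size alongside the p-value. The same test is
reused for pathway (KEGG) maps with N/n/M/m re-scoped to the pathway-
annotated universe. The background N is the annotated universe of the map,
not the full gene catalog; unannotated genes drop out of both N and n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .data_model import AnnotationMap, ConfigurationError

__all__ = [
    "EnrichmentRecord",
    "enrichment_p",
    "bonferroni",
    "rich_factor",
    "enrich",
    "wego_tabulate",
]

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    term_id: str
    label: str
    n_background: int  # N
    n_deg: int  # n
    m_term: int  # M
    m_overlap: int  # m
    p_raw: float
    p_bonferroni: float
    rich_factor: float
    significant: bool


def enrichment_p(n_background: int, n_deg: int, m_term: int, m_overlap: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m_overlap)."""
    N, n, M, m = n_background, n_deg, m_term, m_overlap
    if not (0 <= m <= min(n, M) and M <= N and n <= N):
        raise ValueError(
            f"invalid hypergeometric configuration N={N}, n={n}, M={M}, m={m}"
        )
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def bonferroni(p: float, n_tests: int) -> float:
    """min(1, p * n_tests)."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    return min(1.0, p * n_tests)


def rich_factor(m_overlap: int, m_term: int) -> float:
    """Fraction of a term's genes that are differentially expressed: m/M."""
    if m_term < 1:
        raise ValueError("m_term must be >= 1")
    if not (0 <= m_overlap <= m_term):
        raise ValueError("m_overlap must lie in [0, m_term]")
    return m_overlap / m_term


def enrich(
    deg_genes: Iterable[str], annotation: AnnotationMap, alpha: float = 0.05
) -> list[EnrichmentRecord]:
    """Test every term of the map for over-representation in the DEG set.

    Returns one record per term, sorted by raw p ascending (ties by term
    id); ``significant`` means Bonferroni-corrected p <= ``alpha``. DEGs
    without annotation are dropped from both the background and the DEG
    count (and logged), matching the definition of N.
    """
    if len(annotation) == 0:
        raise ConfigurationError("empty annotation map")
    universe = annotation.universe
    deg = set(deg_genes)
    dropped = len(deg - universe)
    if dropped:
        log.info(
            "enrich[%s]: %d DEGs lack annotation and were dropped from the test",
            annotation.namespace,
            dropped,
        )
    deg &= universe
    N, n = len(universe), len(deg)
    n_tests = len(annotation.term_genes)
    records = []
    for term, genes in annotation.term_genes.items():
        M = len(genes)
        m = len(genes & deg)
        p = enrichment_p(N, n, M, m)
        pb = bonferroni(p, n_tests)
        records.append(
            EnrichmentRecord(
                term_id=term,
                label=annotation.labels.get(term, ""),
                n_background=N,
                n_deg=n,
                m_term=M,
                m_overlap=m,
                p_raw=p,
                p_bonferroni=pb,
                rich_factor=rich_factor(m, M),
                significant=pb <= alpha,
            )
        )
    records.sort(key=lambda r: (r.p_raw, r.term_id))
    return records


_GO_NAMESPACES = ("GO_BP", "GO_CC", "GO_MF")


def wego_tabulate(
    annotations: Iterable[AnnotationMap], gene_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Counts of distinct genes per GO term per named gene set.

    Rows: (namespace, term_id, label, set_name, gene_count), one per term a
    set actually hits — the grouped-bar tabulation of GO-category membership
    across the three GO domains. Genes absent from a namespace's universe
    are skipped with a warning.
    """
    rows = []
    for amap in annotations:
        if amap.namespace not in _GO_NAMESPACES:
            raise ConfigurationError(
                f"wego_tabulate accepts GO namespaces only, got {amap.namespace}"
            )
        universe = amap.universe
        for set_name, genes in gene_sets.items():
            gset = set(genes)
            unknown = gset - universe
            if unknown:
                log.warning(
                    "wego[%s/%s]: %d genes not in annotation universe, skipped",
                    amap.namespace,
                    set_name,
                    len(unknown),
                )
            gset &= universe
            for term in sorted(amap.term_genes):
                count = len(amap.term_genes[term] & gset)
                if count:
                    rows.append(
                        {
                            "namespace": amap.namespace,
                            "term_id": term,
                            "label": amap.labels.get(term, ""),
                            "set_name": set_name,
                            "gene_count": count,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["namespace", "term_id", "label", "set_name", "gene_count"]
    )
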