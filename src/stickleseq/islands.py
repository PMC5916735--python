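"""Enrichment of DE genes in divergence islands.

Divergence islands are genomic intervals concentrating the sequence
variants that separate marine and freshwater ecotypes.  If expression
divergence tracks sequence divergence, DE genes should overlap those
intervals more often than chance.  The test counts DE genes with >= 1 bp
of island overlap and compares the observed count k against the
gene-count expectation ``lambda = n_de * m_island / n_total`` with a
Poisson upper tail; a hypergeometric upper tail (draw n_de genes from
n_total with m_island marked) is reported alongside as the
finite-population companion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import stats
from scipy.special import gammainc, gammaincc

from .io import GeneAnnotation, InputError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    n_total: int          # annotated genes
    m_island: int         # genes overlapping islands
    n_de: int             # DE genes
    k_observed: int       # DE genes overlapping islands
    lambda_expected: float
    pvalue: float         # Poisson tail
    alt_pvalue: float     # hypergeometric tail
    alternative: str = "enrichment"

    FIELDS = [
        "n_total", "m_island", "n_de", "k_observed",
        "lambda_expected", "pvalue", "alt_pvalue", "alternative",
    ]

    def as_row(self) -> dict:
        return {f: getattr(self, f) for f in self.FIELDS}


def count_island_genes(
    annotation: GeneAnnotation,
    islands: GeneAnnotation,
    de_gene_ids: set[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Gene ids overlapping any island by >= 1 bp (half-open intervals).

    Returns ``(island_genes, island_de_genes)``; the second set is empty
    when ``de_gene_ids`` is None.  Islands on chromosomes absent from
    the annotation are ignored with a warning.  Each gene is counted
    once no matter how many islands it touches.
    """
    known = set(annotation.chromosomes)
    trees: dict[str, IntervalTree] = {}
    for row in islands.df.itertuples(index=False):
        if row.chrom not in known:
            logger.warning(
                "island %s on unknown chromosome %r ignored", row.gene_id, row.chrom
            )
            continue
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)

    covered: set[str] = set()
    for row in annotation.df.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is not None and tree.overlaps(row.start, row.end):
            covered.add(row.gene_id)
    de_covered = covered & de_gene_ids if de_gene_ids is not None else set()
    return covered, de_covered


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), via the regularized incomplete gamma."""
    if k <= 0:
        return 1.0
    if lam == 0.0:
        return 0.0
    # P(X >= k) = P(Gamma(k, 1) <= lam), the lower regularized gamma
    return float(gammainc(k, lam))


def poisson_enrichment(
    n_total: int,
    m_island: int,
    n_de: int,
    k_observed: int,
    alternative: str = "enrichment",
) -> EnrichmentResult:
    """Poisson (and hypergeometric) test of DE-gene overlap with islands.

    ``lambda = n_de * m_island / n_total`` uses gene-count proportions:
    both the island total and the genome total enter as gene counts, so
    the expectation is the chance number of DE genes falling in islands
    when DE labels are assigned island-blind.
    """
    if m_island > n_total:
        raise InputError("more island genes than annotated genes")
    if n_de > n_total:
        raise InputError("more DE genes than annotated genes")
    if k_observed > min(n_de, m_island):
        raise InputError("observed overlap exceeds min(n_de, m_island)")
    if min(n_total, m_island, n_de, k_observed) < 0 or n_total == 0:
        raise InputError("counts must be non-negative with n_total > 0")
    lam = n_de * m_island / n_total
    if alternative == "enrichment":
        p = poisson_upper_tail(k_observed, lam)
        alt = float(stats.hypergeom.sf(k_observed - 1, n_total, m_island, n_de))
    elif alternative == "depletion":
        p = float(gammaincc(k_observed + 1, lam)) if lam > 0 else 1.0  # P(X <= k)
        alt = float(stats.hypergeom.cdf(k_observed, n_total, m_island, n_de))
    else:
        raise InputError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(
        n_total=int(n_total), m_island=int(m_island), n_de=int(n_de),
        k_observed=int(k_observed), lambda_expected=float(lam),
        pvalue=p, alt_pvalue=alt, alternative=alternative,
    )


def enrichment_from_sets(
    annotation: GeneAnnotation,
    islands: GeneAnnotation,
    de_gene_ids: set[str],
    alternative: str = "enrichment",
) -> EnrichmentResult:
    """Count overlaps from BED-style inputs and run the enrichment test."""
    covered, de_covered = count_island_genes(annotation, islands, de_gene_ids)
    return poisson_enrichment(
        n_total=len(annotation),
        m_island=len(covered),
        n_de=len(de_gene_ids & set(annotation.gene_ids)),
        k_observed=len(de_covered),
        alternative=alternative,
    )
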