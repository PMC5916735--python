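"""Per-chromosome clustering of DE genes via all-pairs intergenic distances.

For every chromosome, the distances between all unordered pairs of gene
positions (interval midpoints) form one array; the same distances
restricted to DE genes form a second.  A Welch two-sample t-test between
the two arrays asks whether DE genes sit systematically closer together
(or further apart) than genes at large.  Because DE pairs are a subset
of all pairs and pair distances sharing a gene are not independent, the
t-test's nominal P-value is approximate; a permutation test that draws
random same-size gene subsets from the chromosome is provided as the
companion null that respects both issues.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneAnnotation, InputError

logger = logging.getLogger(__name__)


@dataclass
class ChromosomeClusteringResult:
    chromosome: str
    n_genes: int
    n_de_genes: int
    mean_dist_all: float
    mean_dist_de: float
    t_statistic: float | None
    pvalue: float | None
    perm_pvalue: float | None = None
    direction: str = "none"          # clustered | dispersed | none

    FIELDS = [
        "chromosome", "n_genes", "n_de_genes", "mean_dist_all", "mean_dist_de",
        "t_statistic", "pvalue", "perm_pvalue", "direction",
    ]

    def as_row(self) -> dict:
        return {f: getattr(self, f) for f in self.FIELDS}


# ---------------------------------------------------------------------------
# distance primitives
# ---------------------------------------------------------------------------

def pairwise_distances(positions: np.ndarray) -> np.ndarray:
    """All |x_i - x_j| over unordered pairs i < j (length n(n-1)/2).

    Returns an empty array for fewer than 2 positions.
    """
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        return np.empty(0)
    diff = np.abs(x[:, None] - x[None, :])
    iu = np.triu_indices(x.size, k=1)
    return diff[iu]


def mean_pairwise_distance_fast(positions: np.ndarray) -> tuple[float, int]:
    """Mean of all pairwise distances of *sorted* positions, via prefix sums.

    For sorted x, sum_{i<j}(x_j - x_i) = sum_j x_j (2j - n + 1) with
    0-based j, so the mean needs O(n) work instead of O(n^2) and equals
    the brute-force mean exactly.
    """
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        raise InputError("need at least 2 positions")
    if np.any(np.diff(x) < 0):
        raise InputError("positions must be sorted ascending")
    n = x.size
    coef = 2.0 * np.arange(n) - n + 1.0
    total = float(np.dot(x, coef))
    count = n * (n - 1) // 2
    return total / count, count


def _pair_sum_stats(x: np.ndarray) -> tuple[float, float, int]:
    """(mean, unbiased variance, count) of pairwise distances of sorted x, O(n)."""
    n = x.size
    count = n * (n - 1) // 2
    coef = 2.0 * np.arange(n) - n + 1.0
    total = float(np.dot(x, coef))
    # sum of squared pair differences: n*sum(x^2) - (sum x)^2
    sq = float(n * np.dot(x, x) - np.sum(x) ** 2)
    mean = total / count
    var = (sq - count * mean**2) / (count - 1) if count > 1 else 0.0
    return mean, max(var, 0.0), count


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def clustering_test(
    annotation: GeneAnnotation,
    de_gene_ids: set[str],
    chromosome: str,
    test: str = "welch",
    alpha: float = 0.05,
) -> ChromosomeClusteringResult:
    """Compare all-pairs distances against DE-pairs distances on one chromosome.

    The DE pair array is a subset of the all-genes pair array (DE genes
    are not excluded from the reference), and the two arrays go into a
    two-sided two-sample t-test -- Welch by default, ``test='pooled'``
    for the equal-variance variant.  With fewer than 2 DE genes, or a
    degenerate DE array (a single pair has no variance), the means are
    reported and the test fields are null.
    """
    sub = annotation.genes_on(chromosome)
    if len(sub) < 2:
        raise InputError(f"chromosome {chromosome!r} has fewer than 2 genes")
    mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(float)
    de_mask = sub["gene_id"].isin(de_gene_ids).to_numpy()
    pos_all = np.sort(mids)
    pos_de = np.sort(mids[de_mask])

    mean_all, var_all, n_pairs_all = _pair_sum_stats(pos_all)
    result = ChromosomeClusteringResult(
        chromosome=chromosome,
        n_genes=len(sub),
        n_de_genes=int(de_mask.sum()),
        mean_dist_all=mean_all,
        mean_dist_de=float("nan"),
        t_statistic=None,
        pvalue=None,
    )
    if pos_de.size < 2:
        logger.info("chromosome %s: <2 DE genes, test skipped", chromosome)
        return result
    mean_de, var_de, n_pairs_de = _pair_sum_stats(pos_de)
    result.mean_dist_de = mean_de
    if n_pairs_de < 2 or var_de == 0.0 or var_all == 0.0:
        return result
    t, p = stats.ttest_ind_from_stats(
        mean_all, math.sqrt(var_all), n_pairs_all,
        mean_de, math.sqrt(var_de), n_pairs_de,
        equal_var=(test == "pooled"),
    )
    result.t_statistic = float(t)
    result.pvalue = float(p)
    if p < alpha:
        result.direction = "clustered" if mean_de < mean_all else "dispersed"
    return result


def permutation_clustering_test(
    annotation: GeneAnnotation,
    de_gene_ids: set[str],
    chromosome: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation P for the DE mean pair distance on one chromosome.

    The statistic is the mean pairwise distance among DE genes; the null
    draws uniform random gene subsets of the same size from the
    chromosome.  Two-sided:
    ``P = (1 + #{|perm - null_mean| >= |obs - null_mean|}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; permutation P will be coarse")
    sub = annotation.genes_on(chromosome)
    pos = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(float)
    de_mask = sub["gene_id"].isin(de_gene_ids).to_numpy()
    m = int(de_mask.sum())
    if m < 2 or pos.size < 2:
        raise InputError("need at least 2 DE genes and 2 genes on the chromosome")
    obs, _ = mean_pairwise_distance_fast(np.sort(pos[de_mask]))
    perm = _permuted_subset_means(pos, m, n_perm, np.random.default_rng(seed))
    null_mean = perm.mean()
    extreme = np.abs(perm - null_mean) >= abs(obs - null_mean)
    return float((1 + int(extreme.sum())) / (n_perm + 1))


def _permuted_subset_means(
    pos: np.ndarray, m: int, n_perm: int, rng: np.random.Generator, chunk: int = 2000
) -> np.ndarray:
    """Mean pairwise distance for ``n_perm`` random size-m subsets (vectorized)."""
    n = pos.size
    coef = 2.0 * np.arange(m) - m + 1.0
    denom = m * (m - 1) / 2.0
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # random subsets without replacement via row-wise argpartition of random keys
        keys = rng.random((b, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        subs = np.sort(pos[idx], axis=1)
        out[done : done + b] = subs @ coef / denom
        done += b
    return out


def cluster_all_chromosomes(
    annotation: GeneAnnotation,
    de_gene_ids: set[str],
    test: str = "welch",
    alpha: float = 0.05,
    n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the clustering test on every chromosome with >= 2 genes."""
    rows = []
    rng = np.random.default_rng(seed)
    for chrom in annotation.chromosomes:
        sub = annotation.genes_on(chrom)
        if len(sub) < 2:
            logger.info("chromosome %s has <2 genes, skipped", chrom)
            continue
        res = clustering_test(annotation, de_gene_ids, chrom, test=test, alpha=alpha)
        if n_perm > 0 and res.n_de_genes >= 2:
            res.perm_pvalue = permutation_clustering_test(
                annotation, de_gene_ids, chrom, n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
        rows.append(res.as_row())
    return pd.DataFrame(rows, columns=ChromosomeClusteringResult.FIELDS)
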