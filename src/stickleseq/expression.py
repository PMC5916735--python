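"""Normalization and two-group differential-expression testing.

The testing path is the classic conditioned negative-binomial exact test
for two-group designs with a single common dispersion, preceded by
trimmed-mean-of-M-values (TMM) normalization, followed by
Benjamini-Hochberg FDR adjustment.  Tagwise/trended dispersion shrinkage
and GLM-based testing are deliberately out of scope: with biological
replicates and a two-group design, the common-dispersion exact test is
the textbook route, and every quantity it reports (logFC, logCPM,
P-value, FDR) is well defined and reproducible from the maths below.

Model: counts for gene g in sample s are NB with mean
``mu_gs = N_s * 2^(x_g) / 1e6`` (N_s the effective library size, x_g the
log2-CPM abundance) and variance ``mu + phi * mu^2``; ``phi = 0``
degenerates to Poisson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io import CountMatrix, InputError


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample TMM scaling of library sizes; geometric mean is 1."""

    factors: pd.Series
    library_size: pd.Series

    @property
    def effective_library_size(self) -> pd.Series:
        return self.library_size * self.factors


@dataclass
class DEResult:
    """Per-gene DE table: logFC, logCPM, P-value, BH FDR and a DE flag."""

    table: pd.DataFrame = field(repr=False)
    fdr_threshold: float = 0.05
    dispersion: float | None = None

    COLUMNS = ["gene_id", "logFC", "logCPM", "pvalue", "fdr", "is_de"]

    @property
    def n_de(self) -> int:
        return int(self.table["is_de"].sum())

    @property
    def n_up(self) -> int:
        """DE genes with higher expression in group B (positive logFC)."""
        return int((self.table["is_de"] & (self.table["logFC"] > 0)).sum())

    @property
    def n_down(self) -> int:
        return int((self.table["is_de"] & (self.table["logFC"] < 0)).sum())

    def de_gene_ids(self) -> set[str]:
        return set(self.table.loc[self.table["is_de"], "gene_id"])


# ---------------------------------------------------------------------------
# CPM
# ---------------------------------------------------------------------------

def cpm(
    matrix: CountMatrix,
    log: bool = False,
    prior_count: float = 0.5,
    norm_factors: NormalizationFactors | None = None,
) -> pd.DataFrame:
    """Counts per million (optionally log2, with a pseudo-count).

    Linear mode: ``count / effective_library_size * 1e6``.  Log mode:
    ``log2((count + prior) / (effective_library_size + 2 * prior) * 1e6)``.
    """
    lib = matrix.library_size if norm_factors is None else norm_factors.effective_library_size
    lib = lib.to_numpy(dtype=float)
    counts = matrix.counts.to_numpy(dtype=float)
    if log:
        vals = np.log2((counts + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    else:
        vals = counts / lib * 1e6
    return pd.DataFrame(vals, index=matrix.gene_ids, columns=matrix.sample_ids)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    matrix: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper-quartile CPM is closest
    to the mean upper-quartile.  For each sample, M (log2 CPM ratio vs
    reference) and A (average log2 CPM) are computed over genes with
    non-zero counts in both samples; the top/bottom ``trim_m`` by M and
    ``trim_a`` by A are discarded and the factor is 2 to the
    precision-weighted mean of the surviving M-values.  Factors are
    rescaled to geometric mean 1, so a pure sequencing-depth difference
    is absorbed by the library size, not the factor.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    lib = matrix.library_size.to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        bad = matrix.sample_ids[counts.sum(axis=0) == 0][0]
        raise InputError(f"sample {bad!r} has all-zero counts; cannot normalize")
    cpm_mat = counts / lib * 1e6
    uq = np.percentile(cpm_mat, 75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    for s in range(counts.shape[1]):
        if s == ref:
            continue
        factors[s] = 2.0 ** _tmm_one(
            counts[:, s], counts[:, ref], lib[s], lib[ref], trim_m, trim_a
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        pd.Series(factors, index=matrix.sample_ids), matrix.library_size.copy()
    )


def _tmm_one(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.allclose(m, m[0]):
        return float(m[0])
    lo_m, hi_m = np.quantile(m, [trim_m, 1.0 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1.0 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


# ---------------------------------------------------------------------------
# common dispersion (method of moments)
# ---------------------------------------------------------------------------

def estimate_common_dispersion(
    matrix: CountMatrix,
    norm_factors: NormalizationFactors | None = None,
    min_mean: float = 1.0,
    trim: float = 0.20,
) -> float:
    """Moment estimate of the common NB dispersion phi (variance = mu + phi mu^2).

    Counts are scaled to a common library size; for each gene the pooled
    within-group sample variance s2 and grand mean mu give
    ``phi_g = max(0, (s2 - mu) / mu^2)``, and the common value is the
    ``trim``-trimmed mean of phi_g over genes whose mean scaled count is
    at least ``min_mean``.
    """
    lib = matrix.library_size if norm_factors is None else norm_factors.effective_library_size
    lib = lib.to_numpy(dtype=float)
    n_rep = matrix.group.value_counts()
    if (n_rep < 2).all():
        raise InputError(
            "no group has replicates; dispersion cannot be estimated - supply phi explicitly"
        )
    common = np.exp(np.mean(np.log(lib)))
    z = matrix.counts.to_numpy(dtype=float) * (common / lib)

    a, b = matrix.group_levels
    idx_a = matrix.group.to_numpy() == a
    var_parts, dof = [], 0
    for idx in (idx_a, ~idx_a):
        n = int(idx.sum())
        if n >= 2:
            var_parts.append(z[:, idx].var(axis=1, ddof=1) * (n - 1))
            dof += n - 1
    s2 = sum(var_parts) / dof
    mu = z.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_g = np.maximum(0.0, (s2 - mu) / mu**2)
    phi_g = phi_g[mu >= min_mean]
    if phi_g.size == 0:
        return 0.0
    return float(stats.trim_mean(phi_g, trim))


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------

def nb_exact_test(
    matrix: CountMatrix,
    dispersion: float,
    norm_factors: NormalizationFactors | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Conditioned two-group NB exact test for every gene.

    Counts are linearly scaled to the common (geometric-mean) effective
    library size and rounded to integer pseudo-counts.  For a gene with
    group sums ``(y_a, y_b)`` and total ``s``, the null conditional
    distribution of the split is formed from the NB sum distributions
    ``NB(n_a mu, phi / n_a)`` and ``NB(n_b mu, phi / n_b)`` with
    ``mu = s / (n_a + n_b)``; the two-sided P-value doubles the smaller
    of the two tails (each including the observed split), capped at 1.
    ``phi = 0`` degenerates to the conditional binomial test.

    Returns a frame with ``gene_id``, ``logFC`` (group B over group A),
    ``logCPM``, ``pvalue`` and ``testable`` (False when the gene has no
    reads at all: P = 1, logFC = 0).
    """
    if dispersion < 0:
        raise InputError("dispersion must be >= 0")
    lib = matrix.library_size if norm_factors is None else norm_factors.effective_library_size
    lib = lib.to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(lib))))
    pseudo = np.rint(matrix.counts.to_numpy(dtype=float) * (common / lib)).astype(np.int64)

    a, b = matrix.group_levels
    idx_a = matrix.group.to_numpy() == a
    n_a, n_b = int(idx_a.sum()), int((~idx_a).sum())
    y_a = pseudo[:, idx_a].sum(axis=1)
    y_b = pseudo[:, ~idx_a].sum(axis=1)

    pvals = np.ones(len(y_a))
    for g in range(len(y_a)):
        pvals[g] = _exact_pvalue(int(y_a[g]), int(y_b[g]), n_a, n_b, dispersion)

    # stabilized logFC: half a pseudo-count per sample in each group
    logfc = (
        np.log2(y_b + 0.5 * n_b * 1.0) - np.log2(y_a + 0.5 * n_a * 1.0)
        - np.log2(n_b / n_a)
    )
    total = y_a + y_b
    untestable = total == 0
    logfc[untestable] = 0.0
    logcpm = np.log2(
        (total / (n_a + n_b) + prior_count) / (common + 2.0 * prior_count) * 1e6
    )
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "logFC": logfc,
            "logCPM": logcpm,
            "pvalue": pvals,
            "testable": ~untestable,
        }
    ).reset_index(drop=True)


def _exact_pvalue(y_a: int, y_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact P for one gene (tails include the observed split)."""
    s = y_a + y_b
    if s == 0:
        return 1.0
    if phi == 0.0:
        # conditioning two Poissons on their sum gives a binomial split
        p_b = n_b / (n_a + n_b)
        lower = stats.binom.cdf(y_b, s, p_b)
        upper = stats.binom.sf(y_b - 1, s, p_b)
        return float(min(1.0, 2.0 * min(lower, upper)))
    mu = s / (n_a + n_b)
    r_a, r_b = n_a / phi, n_b / phi
    k = np.arange(s + 1)  # candidate values of y_b
    logp = stats.nbinom.logpmf(k, r_b, r_b / (r_b + n_b * mu)) + stats.nbinom.logpmf(
        s - k, r_a, r_a / (r_a + n_a * mu)
    )
    logp -= logsumexp(logp)
    prob = np.exp(logp)
    lower = prob[: y_b + 1].sum()
    upper = prob[y_b:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues, n_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    ``n_total`` (>= len(pvalues)) sets the total number of tests when the
    input is a top-k excerpt of a larger family, e.g. the smallest k
    P-values of N tests; the step-up minimum is then taken within the
    excerpt, which is exact whenever the excluded tail does not lower the
    running minimum (true for any excerpt containing the k smallest).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("pvalues must be one-dimensional")
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise InputError("pvalues must lie in [0, 1]")
    n = n_total if n_total is not None else p.size
    if n < p.size:
        raise InputError(f"n_total ({n}) smaller than number of pvalues ({p.size})")
    if p.size == 0:
        return np.empty(0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, p.size + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# full DE wrapper
# ---------------------------------------------------------------------------

def de_analysis(
    matrix: CountMatrix,
    fdr_threshold: float = 0.05,
    dispersion: float | str = "auto",
    prior_count: float = 0.5,
) -> DEResult:
    """TMM -> common dispersion -> NB exact test -> BH FDR, in one call."""
    factors = tmm_factors(matrix)
    phi = (
        estimate_common_dispersion(matrix, factors)
        if dispersion == "auto"
        else float(dispersion)
    )
    table = nb_exact_test(matrix, phi, factors, prior_count=prior_count)
    table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
    table["is_de"] = (table["fdr"] < fdr_threshold) & table["testable"]
    return DEResult(table, fdr_threshold=fdr_threshold, dispersion=phi)


# ---------------------------------------------------------------------------
# leading-logFC MDS
# ---------------------------------------------------------------------------

def mds_leading_logfc(logcpm: pd.DataFrame, top_n: int = 500, k: int = 2) -> pd.DataFrame:
    """Classical MDS of samples on leading-logFC distances.

    The distance between two samples is the root-mean-square of the
    ``top_n`` largest absolute logCPM differences for that pair -- the
    genes that most distinguish the pair dominate, which is what makes
    replicate groups cluster.  Coordinates come from double-centering
    the squared distance matrix and scaling the top eigenvectors by the
    root of their eigenvalues; each axis's sign is fixed by making the
    first sample's coordinate non-negative.
    """
    x = logcpm.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 3:
        raise InputError("MDS needs at least 3 samples")
    top_n = min(top_n, x.shape[0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (x[:, i] - x[:, j]) ** 2
            lead = np.partition(diff2, x.shape[0] - top_n)[-top_n:]
            d[i, j] = d[j, i] = np.sqrt(lead.mean())
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ (d**2) @ j_mat
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-9 * abs(eigval[0]))
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} dimensions instead of {k}"
        )
        k = n_pos
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    for axis in range(k):
        if coords[0, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return pd.DataFrame(
        coords, index=logcpm.columns, columns=[f"dim{i + 1}" for i in range(k)]
    )
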