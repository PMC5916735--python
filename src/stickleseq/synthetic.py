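"""Synthetic genomes, divergence islands and NB count matrices.

The generator emulates the data regime of a marine-vs-freshwater gill
RNA-seq comparison in three-spined stickleback: ~25k genes on the 21
chromosome-scale scaffolds of the Ensembl BROAD S1 assembly, 4 + 4
sequencing libraries of ~18-29 M mapped reads, negative-binomial counts
with a common dispersion, and a planted DE fraction of ~13% split
between genes up in the marine and up in the freshwater group.  Every
operation is deterministic under a fixed seed, and ground-truth DE
labels and log fold changes are returned alongside the counts so that
downstream stages can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneAnnotation, InputError
from .islands import count_island_genes

# chromosome-scale scaffolds of the stickleback reference assembly
# (Ensembl BROAD S1): (name, length in bp, number of annotated genes)
STICKLEBACK_CHROMOSOMES: list[tuple[str, int, int]] = [
    ("groupI", 28_185_914, 1647), ("groupII", 23_295_652, 1158),
    ("groupIII", 16_798_506, 1226), ("groupIV", 32_632_948, 1719),
    ("groupV", 12_251_397, 980), ("groupVI", 17_083_675, 965),
    ("groupVII", 27_937_443, 1726), ("groupVIII", 19_368_704, 1177),
    ("groupIX", 20_249_479, 1374), ("groupX", 15_657_440, 1050),
    ("groupXI", 16_706_052, 1344), ("groupXII", 18_401_067, 1301),
    ("groupXIII", 20_083_130, 1303), ("groupXIV", 15_246_461, 984),
    ("groupXV", 16_198_764, 1026), ("groupXVI", 18_115_788, 1063),
    ("groupXVII", 14_603_141, 929), ("groupXVIII", 16_282_716, 1020),
    ("groupXIX", 20_240_660, 1373), ("groupXX", 19_732_071, 1259),
    ("groupXXI", 11_717_487, 599),
]

# mapped-read totals of the 4 freshwater (F) and 4 marine (M) libraries
FRESHWATER_LIBRARY_SIZES = (24_692_145, 28_960_967, 26_307_475, 23_609_866)
MARINE_LIBRARY_SIZES = (17_993_109, 18_161_521, 18_489_001, 19_450_343)


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome layout and gene-placement rules for a synthetic genome."""

    chromosome_names: tuple[str, ...]
    chromosome_lengths: tuple[int, ...]
    n_genes_per_chromosome: tuple[int, ...]
    gene_length_range: tuple[int, int] = (1_000, 20_000)
    placement_mode: str = "uniform"        # uniform | clustered
    cluster_count: int = 5
    cluster_spread: float = 100_000.0      # bp dispersal scale around cluster centers
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.chromosome_names) == len(self.chromosome_lengths)
                == len(self.n_genes_per_chromosome)):
            raise InputError("chromosome name/length/gene-count lists differ in length")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise InputError("chromosome lengths must be positive")
        if any(n < 0 for n in self.n_genes_per_chromosome):
            raise InputError("gene counts must be non-negative")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise InputError("gene_length_range must satisfy 0 < min <= max")
        if hi > min(self.chromosome_lengths):
            raise InputError("max gene length exceeds a chromosome length")
        if self.placement_mode not in ("uniform", "clustered"):
            raise InputError(f"unknown placement_mode {self.placement_mode!r}")
        if self.placement_mode == "clustered" and (
            self.cluster_count < 1 or self.cluster_spread <= 0
        ):
            raise InputError("clustered mode needs cluster_count >= 1 and cluster_spread > 0")


@dataclass(frozen=True)
class ExpressionSpec:
    """Two-group NB expression regime with planted DE structure.

    Group labels sort as (A, B); the planted log2 fold change is applied
    to group B, so a positive true logFC means higher expression in B.
    Defaults mirror the study regime: freshwater (F) as group A, marine
    (M) as group B, 4 + 4 libraries at the real mapped-read depths, a
    13.3% DE fraction with 43.7% of DE genes up in the marine group, and
    planted |log2 FC| ~ N(2, 0.5).
    """

    n_samples_group_a: int = 4
    n_samples_group_b: int = 4
    group_labels: tuple[str, str] = ("F", "M")
    library_sizes: tuple[int, ...] = FRESHWATER_LIBRARY_SIZES + MARINE_LIBRARY_SIZES
    baseline_logcpm: tuple[float, float] = (4.0, 2.0)     # mean, sd of log2 CPM
    dispersion: float = 0.1                               # phi; var = mu + phi mu^2
    de_fraction: float = 2982 / 22456
    logfc: tuple[float, float] = (2.0, 0.5)               # mean magnitude, sd
    up_fraction: float = 1304 / 2982                      # DE genes up in group B
    de_placement: str = "random"       # random | clustered | island_linked
    de_cluster_count: int = 5
    island_odds: float = 3.0           # odds multiplier for island-linked placement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_group_a < 1 or self.n_samples_group_b < 1:
            raise InputError("each group needs at least one sample")
        if tuple(sorted(self.group_labels)) != tuple(self.group_labels):
            raise InputError("group_labels must be given in sorted (A, B) order")
        n = self.n_samples_group_a + self.n_samples_group_b
        if len(self.library_sizes) != n:
            raise InputError(f"need {n} library sizes, got {len(self.library_sizes)}")
        if any(l <= 0 for l in self.library_sizes):
            raise InputError("library sizes must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise InputError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise InputError("dispersion must be >= 0")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise InputError("up_fraction must lie in [0, 1]")
        if self.de_placement not in ("random", "clustered", "island_linked"):
            raise InputError(f"unknown de_placement {self.de_placement!r}")


def default_genome_spec(seed: int = 0, **overrides) -> GenomeSpec:
    """The full 21-chromosome stickleback-scale genome (25,223 genes)."""
    names, lengths, counts = zip(*STICKLEBACK_CHROMOSOMES)
    spec = GenomeSpec(
        chromosome_names=names,
        chromosome_lengths=lengths,
        n_genes_per_chromosome=counts,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def scaled_genome_spec(n_genes: int, seed: int = 0, **overrides) -> GenomeSpec:
    """A genome with the same chromosome proportions scaled to ~n_genes genes."""
    names, lengths, counts = zip(*STICKLEBACK_CHROMOSOMES)
    total = sum(counts)
    scaled = tuple(max(2, round(c * n_genes / total)) for c in counts)
    spec = GenomeSpec(
        chromosome_names=names,
        chromosome_lengths=lengths,
        n_genes_per_chromosome=scaled,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(spec: GenomeSpec) -> GeneAnnotation:
    """Draw gene intervals: i.i.d. uniform midpoints, or Matern-style clusters.

    Clustered mode draws ``cluster_count`` centers uniformly per
    chromosome and gene midpoints normal around a random center,
    truncated (by resampling) to the chromosome.  Gene lengths are
    uniform in ``gene_length_range``; gene bodies may overlap.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range
    frames = []
    for chrom, length, n in zip(
        spec.chromosome_names, spec.chromosome_lengths, spec.n_genes_per_chromosome
    ):
        if n == 0:
            continue
        if n * lo > length:
            raise InputError(
                f"cannot place {n} genes of >= {lo} bp on chromosome {chrom!r} "
                f"({length} bp)"
            )
        if spec.placement_mode == "uniform":
            mids = rng.uniform(0, length, n)
        else:
            centers = rng.uniform(0, length, spec.cluster_count)
            which = rng.integers(0, spec.cluster_count, n)
            mids = centers[which] + rng.normal(0, spec.cluster_spread, n)
            bad = (mids < 0) | (mids > length)
            while bad.any():   # truncated normal by resampling
                mids[bad] = centers[which[bad]] + rng.normal(0, spec.cluster_spread, int(bad.sum()))
                bad = (mids < 0) | (mids > length)
        mids = np.floor(mids).astype(np.int64)
        glen = rng.integers(lo, hi + 1, n)
        start = np.maximum(0, mids - glen // 2)
        end = np.minimum(length, start + glen)
        start = np.maximum(0, np.where(end - start < glen, end - glen, start))
        order = np.argsort(mids, kind="mergesort")
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": start[order],
            "end": end[order],
            "gene_id": [f"{chrom}_g{i:05d}" for i in range(n)],
        }))
    if not frames:
        return GeneAnnotation.from_frame(
            pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])
        )
    return GeneAnnotation.from_frame(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# islands
# ---------------------------------------------------------------------------

def simulate_islands(
    annotation: GeneAnnotation,
    n_islands: int,
    island_length: int,
    seed: int = 0,
    chromosome_lengths: dict[str, int] | None = None,
    max_retries: int = 1_000,
) -> tuple[GeneAnnotation, set[str]]:
    """Place non-overlapping island intervals; report genes they cover.

    Chromosomes are chosen with probability proportional to length (by
    default the maximum gene end per chromosome stands in for the
    length).  Returns the island intervals and the set of gene ids
    overlapping at least one island by >= 1 bp.
    """
    if chromosome_lengths is None:
        chromosome_lengths = {
            c: int(annotation.genes_on(c)["end"].max()) for c in annotation.chromosomes
        }
    if n_islands == 0:
        empty = GeneAnnotation.from_frame(
            pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])
        )
        return empty, set()
    chroms = list(chromosome_lengths)
    lengths = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    if island_length >= lengths.min():
        raise InputError("island_length must be shorter than every chromosome")
    rng = np.random.default_rng(seed)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    records = []
    for i in range(n_islands):
        for attempt in range(max_retries):
            c = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
            start = int(rng.integers(0, chromosome_lengths[c] - island_length + 1))
            end = start + island_length
            if all(end <= s or start >= e for s, e in placed[c]):
                placed[c].append((start, end))
                records.append((c, start, end, f"island_{i:04d}"))
                break
        else:
            raise InputError(
                f"could not place island {i} without overlap after {max_retries} retries"
            )
    islands = GeneAnnotation.from_frame(
        pd.DataFrame(records, columns=["chrom", "start", "end", "gene_id"])
    )
    covered, _ = count_island_genes(annotation, islands)
    return islands, covered


# ---------------------------------------------------------------------------
# DE labels and counts
# ---------------------------------------------------------------------------

def place_de_labels(
    annotation: GeneAnnotation,
    n_de: int,
    mode: str,
    rng: np.random.Generator,
    islands: GeneAnnotation | None = None,
    island_odds: float = 3.0,
    n_clusters: int = 5,
) -> np.ndarray:
    """Choose which genes carry a planted DE effect.

    ``random`` samples uniformly without replacement; ``clustered``
    grows equal-quota groups of genes around randomly chosen focal
    genes, taking nearest same-chromosome neighbours first;
    ``island_linked`` samples without replacement with sampling weight
    ``island_odds`` for island-overlapping genes and 1 otherwise.
    Returns a boolean mask over the (sorted) annotation.
    """
    n = len(annotation)
    if n_de > n:
        raise InputError("more DE genes requested than genes available")
    mask = np.zeros(n, dtype=bool)
    if n_de == 0:
        return mask
    if mode == "random":
        mask[rng.choice(n, size=n_de, replace=False)] = True
    elif mode == "clustered":
        chroms = annotation.df["chrom"].to_numpy()
        mids = annotation.midpoints.to_numpy()
        centers = rng.choice(n, size=min(n_clusters, n_de), replace=False)
        quotas = np.full(len(centers), n_de // len(centers))
        quotas[: n_de % len(centers)] += 1
        taken = np.zeros(n, dtype=bool)
        for c, q in zip(centers, quotas):
            same = np.flatnonzero((chroms == chroms[c]) & ~taken)
            near = same[np.argsort(np.abs(mids[same] - mids[c]), kind="mergesort")][:q]
            taken[near] = True
        # top up from anywhere if chromosomes ran out of free genes
        short = n_de - int(taken.sum())
        if short > 0:
            free = np.flatnonzero(~taken)
            taken[rng.choice(free, size=short, replace=False)] = True
        mask = taken
    elif mode == "island_linked":
        if islands is None:
            raise InputError("island_linked placement requires islands")
        covered, _ = count_island_genes(annotation, islands)
        w = np.where(annotation.gene_ids.isin(covered).to_numpy(), island_odds, 1.0)
        mask[rng.choice(n, size=n_de, replace=False, p=w / w.sum())] = True
    else:
        raise InputError(f"unknown de_placement {mode!r}")
    return mask


def simulate_counts(
    annotation: GeneAnnotation,
    spec: ExpressionSpec,
    islands: GeneAnnotation | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts for a two-group design with planted DE effects.

    Gene g in sample s is NB with mean
    ``mu_gs = library_size_s * 2^(baseline_g + logFC_g * [g DE] * [s in B]) / 1e6``
    and variance ``mu + phi mu^2`` (Poisson when phi = 0).  Returns the
    count matrix and a ground-truth frame (gene_id, is_de, true_logfc).
    """
    rng = np.random.default_rng(spec.seed)
    n = len(annotation)
    n_a, n_b = spec.n_samples_group_a, spec.n_samples_group_b
    label_a, label_b = spec.group_labels
    sample_ids = [f"{label_a}{i + 1}" for i in range(n_a)] + [
        f"{label_b}{i + 1}" for i in range(n_b)
    ]
    group = pd.Series([label_a] * n_a + [label_b] * n_b, index=sample_ids)
    lib = np.asarray(spec.library_sizes, dtype=float)

    baseline = rng.normal(spec.baseline_logcpm[0], spec.baseline_logcpm[1], n)
    n_de = round(spec.de_fraction * n)
    de_mask = place_de_labels(
        annotation, n_de, spec.de_placement, rng,
        islands=islands, island_odds=spec.island_odds,
        n_clusters=spec.de_cluster_count,
    )
    true_logfc = np.zeros(n)
    de_idx = np.flatnonzero(de_mask)
    if de_idx.size:
        magnitude = np.abs(rng.normal(spec.logfc[0], spec.logfc[1], de_idx.size))
        n_up = round(spec.up_fraction * de_idx.size)
        signs = np.full(de_idx.size, -1.0)
        signs[rng.choice(de_idx.size, size=n_up, replace=False)] = 1.0
        true_logfc[de_idx] = signs * magnitude

    in_b = np.array([0.0] * n_a + [1.0] * n_b)
    log2_abund = baseline[:, None] + true_logfc[:, None] * in_b[None, :]
    mu = lib[None, :] * np.exp2(log2_abund) / 1e6
    if spec.dispersion == 0.0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / spec.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    matrix = CountMatrix(
        pd.DataFrame(counts, index=annotation.gene_ids.to_numpy(), columns=sample_ids),
        group,
        pd.Series(lib, index=sample_ids),
    )
    truth = pd.DataFrame({
        "gene_id": annotation.gene_ids.to_numpy(),
        "is_de": de_mask,
        "true_logfc": true_logfc,
    })
    return matrix, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
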