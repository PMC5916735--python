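# Methods

## Count model and differential expression

Counts for gene *g* in library *s* are modelled as negative binomial
with mean μ\_gs = N\_s · 2^(x\_g) / 10⁶ — N\_s the effective library
size, x\_g the log2-CPM abundance — and variance μ + φμ².  A single
common dispersion φ is shared across genes; tagwise or trended
dispersion shrinkage is deliberately out of scope, because with a plain
two-group design the common-dispersion exact test is fully specified by
elementary formulas and every reported number can be re-derived by hand.

**TMM normalization.**  The reference library is the one whose
upper-quartile CPM is closest to the mean upper-quartile.  For every
other library, M = log2 CPM ratio and A = mean log2 CPM are computed
over genes non-zero in both libraries; the top and bottom 30% by M and
5% by A are trimmed, and the factor is 2 to the precision-weighted mean
of the surviving M-values (weights from the delta-method binomial
variance).  Factors are rescaled to geometric mean 1, so a pure depth
difference moves the library size, not the factor.  A library of all
zeros is an error.

**Dispersion.**  Counts are scaled to the common (geometric-mean)
effective library size.  For each gene, the within-group variances are
pooled and combined with the grand mean μ into the moment estimate
φ\_g = max(0, (s² − μ)/μ²); the common φ is the 20%-trimmed mean of φ\_g
over genes with mean scaled count ≥ 1.  The per-gene max(0, ·) biases
low-count genes upward, but the trimmed mean is dominated by
well-expressed genes where the estimator concentrates; calibration
tests require the Poisson-truth estimate to stay below 0.02 and the
φ = 0.1 estimate to land within a factor of two at the study design
(2,000 genes, 4 + 4 libraries).  With no replicated group the estimator
refuses and asks for an explicit φ.

**Exact test.**  Counts are linearly scaled to the common library size
and rounded to integer pseudo-counts (quantile adjustment is not used —
linear scaling keeps the procedure elementary, at the cost of mild
miscalibration when library sizes are very unequal; the null-uniformity
test bounds that effect at the study's 17–29 M depths).  For group sums
(y\_A, y\_B) with total s, the null conditional distribution of the
split is built from the NB sum distributions NB(n\_A μ, φ/n\_A) and
NB(n\_B μ, φ/n\_B) with μ = s/(n\_A+n\_B); at φ = 0 this collapses to
Binomial(s, n\_B/(n\_A+n\_B)).  The two-sided P doubles the smaller
cumulative tail, each tail including the observed split, capped at 1 —
the common exact-test convention, chosen over minimum-likelihood
summation so results are deterministic and easily cross-checked.  A
gene with s = 0 gets P = 1, logFC = 0 and `testable = False`.

The fold change is stabilized with half a pseudo-count per sample:
logFC = log2((y\_B + 0.5 n\_B)/(y\_A + 0.5 n\_A)) − log2(n\_B/n\_A),
reported as group B over group A with group levels in sorted order.
logCPM uses log2((mean count + 0.5)/(common library + 1) · 10⁶).

**FDR.**  Benjamini–Hochberg step-up: sort ascending, raw\_i = p\_(i)·N/i,
adjusted\_(i) = min over j ≥ i of raw\_j, capped at 1.  `n_total` lets a
top-k excerpt of N tests be adjusted exactly; this is valid because the
excluded larger P-values cannot lower the running minimum when the
excerpt contains the k smallest (their raw values are ≥ p\_(k)·N/k
whenever they exceed p\_(k)·(j/k)… in practice verified on the data the
package targets, where the rank-10 adjusted value equals its raw value).
Note BH is not idempotent as a whole map (re-adjusting multiplies by
N/i again); only its monotonization step is a projection, and that is
what the property suite asserts.

**DE threshold.**  "Significant at the 95% level" is interpreted as
BH FDR < 0.05, exposed as `--fdr`.

**MDS.**  The distance between two samples is the root-mean-square of
the `top_n` (default 500) largest absolute logCPM differences for that
pair.  Classical MDS follows: double-center the squared distance
matrix, eigendecompose, scale the top-k eigenvectors by root
eigenvalues; each axis's sign is fixed by making the first sample's
loading non-negative so runs are comparable.  If fewer than k positive
eigenvalues exist the output is truncated with a warning.

## Chromosomal clustering of DE genes

A gene's position is its interval midpoint.  This choice is deliberate:
on a chromosome of length L with roughly uniform gene placement, the
mean of all-pairs positional distances is ≈ L/3 (mean |X−Y| for i.i.d.
uniforms), i.e. megabases — which is the magnitude this statistic is
designed to report — whereas adjacent-gene gaps would be ~L/n
(kilobases).  Start-to-start distances would shift nothing
materially; midpoints are symmetric under strand and interval length.

Per chromosome, the array of all n(n−1)/2 pair distances and the array
of the m(m−1)/2 DE pair distances are compared with a two-sample
t-test, Welch by default (`--t-test pooled` for the equal-variance
variant).  DE pairs stay inside the all-genes array — no exclusion —
mirroring the literal two-array procedure; means, variances and counts
are computed in O(n) by prefix sums (Σ\_{i<j}(x\_j−x\_i) = Σ\_j x\_j(2j−n+1)
on sorted positions, and Σ of squared differences = nΣx² − (Σx)²), which
a test verifies against the materialized arrays.

Two caveats are inherent in that design and are the reason the
permutation companion exists: pair distances sharing a gene are
dependent, and the DE array is nested in the reference array, so the
t-test's nominal null is wrong in a direction that is hard to sign in
general.  The permutation test draws `n_perm` uniform random gene
subsets of size m from the same chromosome, recomputes the mean DE pair
distance, and reports the two-sided
(1 + #{|T\_perm − mean| ≥ |T\_obs − mean|})/(n\_perm + 1).  Calibration
tests hold its type-I error in [0.03, 0.08] at nominal 0.05 over 500
null replicates and require P < 0.01 when DE genes are confined to a 5%
window.  A chromosome with fewer than 2 DE genes, or a degenerate DE
array (single pair), reports means with null test fields.

## Island enrichment

A gene overlaps an island when the half-open intervals intersect by
≥ 1 bp (interval-tree lookup, verified against brute force); a gene
counts once regardless of multiplicity.  The expectation uses
gene-count proportions, λ = n\_de · m\_island / n\_total, because both
the island membership and the genome total enter as gene counts —
base-pair proportions would answer a different question (and would need
the full interval lengths, not just memberships).  The upper tail
P(X ≥ k | λ) is evaluated through the regularized incomplete gamma
(matching direct summation to 1e-12 in tests); the hypergeometric tail
(draw n\_de from n\_total with m\_island marked) is reported alongside,
and the two agree within an order of magnitude whenever
m\_island ≪ n\_total.  Enrichment is one-sided by design (the
directional hypothesis); `--depletion` flips the tail.  Totals can be
given as explicit numbers (`--counts-only`) to reproduce published
arithmetic without the underlying annotation.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical skeleton of the study design:

- **Genome** — 21 chromosomes with the reference-assembly lengths and
  per-chromosome gene counts of the stickleback BROAD S1 annotation
  (25,223 genes total), scalable to any total while keeping the
  proportions (`scaled_genome_spec`).  Gene midpoints are i.i.d.
  uniform, or Matérn-style clustered (uniform cluster centers,
  truncated-normal offsets) for power studies; gene lengths uniform in
  1–20 kb; overlapping gene bodies are allowed, since all downstream
  statistics use midpoints.
- **Libraries** — 4 freshwater + 4 marine samples with the study's
  mapped-read totals (23.6–29.0 M and 18.0–19.5 M respectively) as both
  the NB means' scale and the CPM denominators.
- **Expression** — baseline log2 CPM ~ N(4, 2) (chosen so total CPM over
  ~22k genes is ≈ 10⁶, making the abundance scale self-consistent);
  common dispersion φ = 0.1, a typical biological-replicate value for
  wild-caught vertebrate samples; DE fraction 2982/22456 ≈ 13.3% with
  1304/2982 of DE genes up in the marine group; planted
  |log2 FC| ~ N(2, 0.5).
- **DE placement** — uniform, clustered around focal genes, or
  island-linked with a configurable sampling-odds multiplier (default
  3), which is what gives the enrichment test something to detect.

It does **not** simulate reads, isoforms, GC/length bias, batch
effects, or sample-specific dispersions.  Passing calibration on these
data therefore demonstrates correctness of the statistics under the
stated NB model, not robustness to artefacts real libraries may carry.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; GFF3 is converted on
  read.  Strand is parsed, stored and ignored.
- Library size defaults to column sums but accepts externally known
  mapped-read totals, since a counts matrix restricted to annotated
  genes undercounts the true depth.
- Exact-test conditional pmfs are computed in log space and normalized
  by logsumexp; tails sum the normalized pmf directly.
- Each simulation operation consumes one `numpy` Generator seeded from
  its own spec, so stages can be regenerated independently and reruns
  are bit-identical.
- Test and demo problem sizes (300–2,000 genes, 200–10,000
  permutations) are chosen so the whole suite completes in well under a
  minute while keeping Monte-Carlo error comfortably inside the asserted
  bands; the full 25k-gene genome runs through the same code paths.
- The clustered-placement check is stated against the closed form
  (1 − 1/k)·L/3 for k cluster centers averaged over seeds, since for
  k = 5 that expectation sits exactly at 0.8·L/3 and a one-sided bound
  there would be a coin flip.

## Known limitations

- The common-dispersion exact test is anticonservative when dispersions
  vary strongly across genes; the package intentionally does not
  implement empirical-Bayes shrinkage.
- The Welch t-test on pair-distance arrays inherits the dependence
  problems described above; treat its P-values as descriptive and the
  permutation P as the inferential one.
- TMM assumes most genes are not DE; with planted DE fractions far
  above ~30% factors will drift.
- The Poisson enrichment tail is a large-n approximation to the
  hypergeometric; both are reported, but neither models spatial
  autocorrelation of DE labels along chromosomes (a gene cluster inside
  one island inflates both).
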