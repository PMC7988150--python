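# Methods

`pmikit` analyses how a brain transcriptome changes while tissue sits at
room temperature after resection — a simulated postmortem interval (PMI).
The package implements the full computational chain: a synthetic-data
generator that encodes the assumed data-generating process, a
replicate-free stability classifier, activity-gene enrichment ratios,
co-expression kernel detection, ordered-bin hypergeometric enrichment,
and PCA ordination. This note records the models, the parameters that
matter, and the design choices that were genuinely open.

## The data-generating model

The generator simulates a single tissue block dissected at 7 time points
(0, 1, 2, 4, 8, 12, 24 h; one replicate each) plus two replicated
two-group designs: fresh vs postmortem (the postmortem group evaluated at
29 h, the typical PMI of brain-bank reference cohorts) and high vs low
electrical-activity cortex (4 replicates per group each).

Four planted gene classes sit on a lognormal FPKM-like baseline
`x(0) = 2^N(5, 1.5)`:

* **neuronal decay** (default 300 genes): `x(t) = x(0)·exp(−λt)` with λ
  lognormal, median 0.15/h (log-sd 0.2). At these rates expression falls
  ~97% by 24 h and is nearly absent at 29 h, matching the rapid,
  near-complete loss of activity-dependent neuronal transcripts in
  postmortem tissue.
* **glial rise** (default 450 genes): `x(t) = x(0)·(1 + a(1 − e^(−t/τ)))`,
  amplitude `a ∈ [2.5, 5]`, `τ ∈ [4, 6] h`. A saturating exponential keeps
  profiles rising through 24 h (glial activation programs continue to
  increase for at least a day) while most of the change happens by ~12 h,
  when microglial/astrocytic activation peaks histologically. The modest
  τ range models a largely shared activation program with gene-to-gene
  amplitude variation.
* **stable background** and **housekeeping** (default 64 reference
  genes): flat in expectation. Housekeeping genes are tracked separately
  because one analysis asks whether classical normalization references
  are in fact PMI-stable.

Every value is multiplied by `2^ε`, `ε ~ N(0, σ)` — multiplicative
log2-normal noise, which preserves positivity and makes fold change the
natural effect scale. The default σ = 0.15 (~11% CV) models the
technical plus local-sampling variability of serial dissections of one
block processed through one library pipeline. This is the decisive free
parameter: a saturating rise spans only ~2 log2 units over these seven
time points (signal SD ≈ 0.7), so at σ ≳ 0.25 the expected within-module
Pearson correlation falls to ~0.89 and no parameterization of the rise
kinetics can clear an r > 0.95 edge threshold; at σ = 0.15 module
recovery is reliable while the classifier still faces a non-trivial
false-positive field (about a fifth of flat genes land in the
indeterminate class). An optional `quality_dip` flag injects extra noise
at 1 h and 4 h to mimic a transient RNA-quality drop at those points;
it is off by default.

The **activity-dependent gene set** is planted as: all neuronal genes,
plus a complement sized so neuronal genes are 71% of the set, split
evenly between glial genes (glial activation genes also differ between
high- and low-activity cortex, and both co-expression kernels should lie
inside the activity set) and the stable background (real activity sets
contain many PMI-stable genes; the enrichment ratio is undefined
without them). Signed fold-change magnitudes are drawn
log-exponentially above the 1.3 detection floor (rate 10, truncated at
4), so ~48% exceed |FC| 1.4 and ~26% exceed 1.5 — the steep thinning
real activity sets show as the cutoff tightens. Non-neuronal activity
genes change in either direction with equal probability.

Determinism: one `numpy` Generator stream per run, seeded from
`cfg.seed`; the planted truth is drawn before any noise, so the time
course and both grouped designs of one config share identical truth.

### What the generator does not emulate

Read-level artifacts (no FASTQ, no alignment or counting noise),
isoform/splicing structure, RNA editing, correlated noise between
adjacent time points, batch effects, and library-size composition bias
beyond what quantile normalization models. Passing tests therefore show
that the statistical chain recovers planted structure under idealized
noise — not that it is robust to every failure mode of real RNA-seq.

## Stability classification without replicates

With one replicate per time point there is no within-gene variance, so
significance comes from a cross-gene mean–variance trend, in the spirit
of local-noise models for low-replicate expression data:

1. `d_t = log2((x_t + c)/(x_0 + c))` per gene for each t > 0
   (pseudocount c = 1 FPKM throughout the package);
2. genes are ordered by mean log2 intensity; per time point a local
   robust scale `σ̂(intensity)` is estimated over a sliding window of
   W = 500 genes as 1.4826 × a two-pass rolling MAD, with a 10⁻⁶ floor
   (the floor is what makes the σ = 0 limit behave: flat genes get
   z = 0, planted genes get arbitrarily large z);
3. `z_t = d_t/σ̂` gives normal two-sided per-time-point p-values,
   combined per gene as the Šidák-corrected best time point,
   `p = 1 − (1 − min_t p_t)^T`;
4. Benjamini–Hochberg FDR across genes.

Calls: **not-stable** iff q ≤ 0.01 *and* max|d_t| ≥ log2(1.3);
**stable** iff the gene clears neither bar; everything else —
significant-but-small or large-but-not-significant — is
**indeterminate**. A third class exists by construction; on default
synthetic data roughly a fifth of genes are indeterminate, which is why
stable + not-stable shares do not sum to 100%.

The min-p combination deliberately rewards a single decisive departure
from baseline rather than an accumulated trend; it is the conservative
choice for monotone kinetics and makes the calls invariant under
relabeling of the t > 0 columns (a property the tests check). The
classifier's defaults (FDR 1%, fold floor 1.3 — the most lenient of the
three activity-set cutoffs, window 500) are config-swappable; validation
is by parameter recovery against planted truth (sensitivity and
specificity ≥ 0.9 across seeds), not by matching any published gene
count.

## Enrichment ratios

The activity-set enrichment among not-stable genes is a ratio of ratios,

    E = (A_ns / A_s) / (N_ns / N_s),

where A counts activity genes and N counts *all* classified genes by
call; indeterminate genes appear in neither ratio. The all-gene
background is the convention that reproduces the published table this
ratio models — (356/99)/(5947/6754) = 4.1 and so on, mean 3.2 over the
1.3/1.4/1.5 cutoffs. With no stable activity genes the ratio is
undefined; the library op raises, and the pipeline reports null with the
counts.

The housekeeping ratio is the mirror image — over-representation among
stable genes, `(hk_s/N_s)/(hk_ns/N_ns)` — reported as +inf when no
housekeeping gene is unstable (serialized as null with an explicit
flag).

Hypergeometric enrichment of a selection is `E = (k/n)/(K/N)` with
upper-tail p `P(X ≥ k)` (scipy's survival function; verified against
exact integer enumeration to 10⁻¹² for N ≤ 60). Ordered-bin enrichment
partitions a ranked gene list (decreasing fresh/postmortem ratio) into
consecutive bins (default 4 × 500) and scores each bin against the
fixed universe of tested genes. The universe defaults to the DE-tested
set — genes expressed in ≥ 1 replicate of each group — the one choice
that is well defined for any input; it is configurable and logged.

## Differential expression

Welch's unequal-variance t-test on log2(x + 1) between groups after
quantile normalization, BH-FDR over tested genes. The quantile
normalization tie rule: tied values within a column receive the mean of
the reference values their ranks span (this preserves column sums but
not the exact multiset; the property tests distinguish the two). The
test choice is deliberately a plain Welch test: with n = 4 vs 4 every
downstream conclusion lives after the DE step, and the test is
swappable. Degenerate zero-variance cases are guarded (equal constant
groups → p = 1). Fold change is sign-encoded (`fc = ratio` if ≥ 1 else
`−1/ratio`) so `|fc| ≥ cutoff` reads naturally in both directions.

"Most downregulated" ranking uses the fresh/postmortem ratio of
pseudocounted means, not the p-value; the two published filter
conventions — (|FC| ≥ 1.5, FDR ≤ 12%) and (p < 0.05, ratio > 2.6) — are
exposed as named presets rather than reconciled.

A note on power: a 4-vs-4 design at σ = 0.15–0.25 cannot detect
|FC| = 1.3 at FDR ≤ 1%. Real activity-dependent gene lists come from
prior, far larger cohorts and enter this analysis as *inputs*. The
pipeline therefore takes its activity sets from gene-set files (written
by the generator from planted truth in simulation mode);
`activity_genes_at_cutoff` derives sets from DE output when a
well-powered comparison is available.

## Co-expression kernels (MCODE)

Genes are linked when their log2 time-course profiles correlate with
r > 0.95 and positive-tail p < 0.001 at n = 7 (t-transform,
`t = r√((n−2)/(1−r²))`, df = n − 2). Three documented choices:

* **log2 profiles**: Pearson on the log scale is invariant to the rate
  constant for exponential kinetics — all decaying genes share one
  log-linear shape — which is exactly the module structure the graph is
  meant to expose.
* **positive correlations only**: falling and rising kernels must stay
  separate, and a signed threshold would merge them.
* **positive-tail p**: the matched test for a positive-only edge rule,
  and the only convention under which r > 0.95 at n = 7 implies
  p < 0.001 (the two-sided value at the boundary is 1.045 × 10⁻³; both
  conventions are available in `correlation_pvalue`, and both
  thresholds are enforced on every edge regardless).

Kernels are extracted with the published MCODE scheme, re-implemented:
vertex weight = (highest k-core of the closed neighbourhood) k ×
that core's density, computed by Batagelj–Žaveršnik min-degree peeling
on plain adjacency sets (validated against a brute-force repeated-
pruning oracle on random graphs); greedy breadth-first expansion from
unvisited seeds in decreasing weight order, admitting neighbours with
weight ≥ seed weight × (1 − vwp); haircut = restrict to the cluster's
2-core; optional fluff (off by default). Cytoscape-plugin defaults
(vwp 0.2, haircut on) are used. Clusters are disjoint by construction,
sorted by density × size with gene-ID tie-breaks for determinism.

Cluster profiles are time-0-normalized per member, averaged with
mean-expression weights (uniform and vertex-weight schemes available —
the published figure this mirrors never defines its weights), with a
weighted SEM using reliability-weight variance and effective sample
size `n_eff = (Σw)²/Σw²`; for equal weights this reduces exactly to the
ordinary ddof = 1 SEM. Direction is the sign of the Spearman
correlation between mean profile and time.

The pipeline's default candidate set for the graph is the activity set
at |FC| ≥ 1.3; the recovery analyses build the graph over all genes so
that both planted modules are recoverable in full.

## Ordination

PCA of samples (or time points) on a gene panel: log2(x + 1), variables
centered and by default scaled to unit variance (zero-variance genes
dropped with a warning), singular-value decomposition, explained
variance ratios summing to 1 over all components. Component signs
follow a fixed convention — the alphabetically first panel gene with a
non-negligible loading gets a non-negative loading — so scores are
stable across backends and reorderings. Group barycenters are mean
score positions; the 80% confidence ellipse of a barycenter comes from
the eigen-decomposition of S/m (S the ddof = 1 sample covariance of the
group's m scores) with semi-axes `√(eigenvalue · χ²₂(0.80))`,
χ²₂(0.80) ≈ 3.2189. Singular covariance is flagged degenerate rather
than erroring. Whether the source analyses scaled variables is not
recorded anywhere; unit-variance scaling (the common R default) was
chosen and is a flag.

## Pipeline and problem sizes

`run_full` chains simulate → DE/ranking/binned enrichment → stability →
enrichment ratios → graph/MCODE/profiles → PCA, writes all intermediate
tables as TSV, the network as GraphML, and one JSON report embedding
config and seed; a rerun with the same config and seed is bit-identical.
Default problem size is 5,000 genes — the smallest universe at which the
module structure (300 + 450 planted genes), the 500-gene variance-trend
window and the 4 × 500 binning all operate at their intended scale; a
full default run takes well under a minute on one core, and the
multi-seed recovery analyses in `scripts/acceptance.py` use 5 seeds.

## Known limitations

* The stability test's Šidák-min-p ignores accumulating monotone trends,
  costing power against slow drifts relative to a trend test.
* The variance-trend window assumes noise depends on intensity only;
  class-dependent noise would bias σ̂ where planted genes cluster in
  intensity.
* The two-pass rolling-MAD scale is an approximation to the windowed MAD
  (exact at the window center for symmetric noise).
* Edge significance at n = 7 is fragile: sample r has ~0.5 SD on the
  Fisher-z scale, so module membership near the 0.95 threshold is
  partly stochastic; the MCODE expansion, not the raw edge list, is
  what makes recovery reliable.
* The fresh-vs-postmortem generator reuses the time-course kinetic laws
  at 29 h; it does not model cohort effects (different subjects, RNA
  quality, library batches) that dominate real fresh/postmortem
  comparisons.
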