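# Methods

## The positional clustering statistic

**Definition.** Two genes are *clustered* when they lie on the same
chromosome and either overlap (or touch) or are separated by at most
`window` intervening base pairs.  The gap between non-overlapping genes
is counted as `later_start − earlier_end − 1`; overlapping or touching
intervals score 0.  Endpoint conventions within ±1 bp are arbitrary —
choosing touching = 0 rather than 1 shifts no biological conclusion at a
10 kb window, but it is fixed and documented here so counts are
reproducible.  Strand is ignored throughout: the criterion is purely
positional.

Two summary statistics are implemented for a gene list resolved against
the annotation:

- **pairs** (default): the number of unordered clustered pairs;
- **genes**: the number of listed genes participating in ≥ 1 pair.

Both phrasings are in circulation for this kind of analysis and they are
not interchangeable (a run of *m* adjacent genes contributes ~*m* to one
and up to *m(m−1)/2* to the other), so the result object always records
both counts and the enrichment table says which metric the null used.
Neither is asserted to reproduce any particular published ratio.

**Null model.** `n_random` (default 500) lists of the same length as the
*resolved* input list are drawn uniformly without replacement from the
full annotated universe and scored identically.  Unresolvable ids are
dropped first (logged) — matching random lists to the raw length would
systematically inflate the null.  Reported:

- ratio = observed / mean(null), undefined (NA) when the null mean is 0;
- empirical p with the add-one estimator `(1 + #{null ≥ obs})/(1 + n_random)`,
  so p can never be 0 and its floor is `1/(n_random+1)` (1/501 at the
  default);
- BH FDR across whatever collection of lists was analysed together.

**Algorithm.** Counting uses a per-chromosome sweep over start-sorted
coordinate arrays: gene *i* pairs with exactly the genes *j > i* whose
start is ≤ `end_i + window + 1`, a contiguous block found by binary
search, making a draw O(n log n).  The tests hold this equal to O(n²)
brute-force enumeration on thousands of random and adversarial instances
(ties, containment, zero-length windows).

**Groupings.** Cluster memberships are the connected components of the
pairwise relation.  On a start-sorted chromosome a component break
occurs exactly where `start_i − max(end_{<i}) − 1 > window`; maximal
unbroken runs are the components (verified against a union-find oracle).
Components with a single gene are omitted and numbering follows
chromosome, then leftmost start.

## Moderated t differential expression

The only design supported is the two-group contrast (mutant vs wild
type), the case the surrounding pipeline needs; `logFC = mean(b) −
mean(a)` with the pooled variance on `d_g = n_a + n_b − 2` df.  The
gene-wise variances are modelled hierarchically with a scaled-inverse-χ²
prior (`d0`, `s0²`); the posterior variance `(d0·s0² + d_g·s²)/(d0+d_g)`
yields a t statistic on `d0 + d_g` df.  The hyperparameters are
estimated by matching the mean and variance of `log s²` to the log-F
distribution the prior implies (digamma/trigamma moment matching, Newton
inversion of the trigamma).  When the observed log-variances are no more
dispersed than sampling noise alone explains, the moment equation has no
positive root and `d0` is treated as unbounded (all variances shrunk to
`s0²`) rather than failing.  `d0 = 0` reduces exactly to the ordinary
pooled t-test and is exposed for that purpose.  The implementation
agrees with the reference R implementation of this model family (limma)
to ~1e-8 relative tolerance in the test suite, and recovers a true
`d0 = 4` within 20 % from 10,000 genes.

Numerical choices: variances below `var_floor` (default 1e-8, i.e.
numerically constant genes) are floored with a logged warning so the
statistic stays defined; p-values are two-sided; `df = inf` falls back
to the normal distribution inside scipy.

**Significance filter.** FDR < 0.15 and |log2FC| > 0.1, both strict, so
a gene at exactly (0.15, 0.1) is excluded and (0.149, 0.101) included.
The thresholds are exposed (`--fdr-max`, `--lfc-min`) because published
analyses vary in both the cutoff values and whether p or FDR was
filtered.

## Hypergeometric overlap and GO

List overlap and GO over-representation both use the upper tail
P(X ≥ k) of the hypergeometric distribution with the annotated gene set
as the universe — not the whole genome, since random-list calibration
and overlap must refer to the same sampling frame ("genes on the chip").
The same machinery serves both so their p-values are directly
comparable.  GO terms are tested exactly as annotated, with no
propagation to ancestor terms; annotations to genes outside the
universe are dropped with a warning.  GO significance: BH FDR < 0.05,
strict.  The tail is computed by `scipy.stats.hypergeom.sf` (log-space
stable) and is tested against exact rational enumeration for every
configuration with a universe ≤ 25.

## Synthetic data: what it emulates and what it does not

The generator lays out `n_chrom × genes_per_chrom` non-overlapping genes
per chromosome with truncated-normal lengths and gaps (floor 100 bp).
Defaults — 5 chromosomes × 2,000 genes, 2 kb ± 1 kb genes, 6 kb ± 4 kb
gaps — give a fly-scale density of about one gene per 8 kb, so a 10 kb
window links most immediate neighbours but few second neighbours;
random 200-gene lists then average ~4 clustered pairs, and the planted
configuration (40 clusters of 5 consecutive genes) produces ratios in
the tens, the regime where this statistic is scientifically
interesting.

Expression: per-gene baselines ~N(8, 1.5²) log2 units, true variances
from the scaled-inverse-χ² prior with `d0 = 4`, `s0 = 0.25` (typical
residual SDs of ~0.2–0.4 log2 units with a realistic heavy upper tail),
3 replicates per group and ±1.0 log2-unit planted effects — a modestly
powered microarray-like design in which per-gene sensitivity at the
default filter is ~60–75 %, deliberately not saturating, so recovery
metrics remain informative.  Planted clusters occupy *consecutive*
annotation genes with intra-cluster gaps ≤ window and > window
separation from every other planted element, guaranteeing the clusters
are exactly the connected components of the planted list and giving a
computable lower bound (≥ size−1 pairs per cluster) on the observed
count.  Replicate counts per group are a free parameter since typical
published designs vary.

The generator does **not** emulate probe-level artefacts, normalization
effects, correlated expression between neighbouring genes under the
null, chromosome-end density gradients, or annotation errors.  Passing
tests therefore demonstrate the statistics are implemented and
calibrated correctly under a clean spatial-null model — not that real
arrays are free of the spatial artefacts (e.g. correlated neighbours)
that can inflate clustering signal in practice; on real data the
random-list null absorbs the static gene layout but not residual
expression correlation.

## Benchmark design

`run_benchmark` simulates one genome and two mutant-vs-wild-type
conditions.  Condition A's upregulated truth is the planted clustered
list (40×5 genes plus 40 singletons by default); its downregulated
truth is 40 random singletons.  Condition B's lists are ~0.32× the size
of A's with `overlap_fraction` (default 0.5) of B's ids drawn from A's
— an asymmetric regulator pair in which the shared targets are a large
share of the smaller list and a small share of the larger one.  The
planted GO term is the shared up-set.  The pipeline then runs blind and
`recovery.json` reports DE sensitivity/specificity, the cluster ratio
and empirical p of the recovered lists, exact-component recovery, the
measured shared fractions and the planted term's FDR.

All randomness flows from one seed: every stage derives a stable
sub-seed (SeedSequence over a digest of the stage name), so a config
re-runs byte-identically; the manifest records config, versions and
seed and contains no timestamps.

## Problem sizes used in the checks

The automated checks run at the scale the defaults define: a
10,000-gene genome for null calibration (50 repeats × 500
randomizations), planted recovery (40×5 clusters, 500 randomizations),
type-I error (5,000–10,000 null genes) and prior recovery
(10,000 genes); sweep/brute-force equality uses 1,000 random instances
of 2–300 genes plus small adversarial cases.  Statistical assertions use
frozen seeds; calibration bands (mean null ratio in [0.9, 1.1], type-I
error inside the 99 % binomial interval, KS uniformity at α = 0.01) are
two-sided properties of the model, not tuned tolerances.

## Known limitations

- Only two-group contrasts; no covariates, paired designs or multi-level
  models.
- The clustering null treats the gene layout as fixed and lists as
  exchangeable; it does not model spatially correlated noise.
- GO analysis ignores the ontology graph structure entirely.
- The `genes` metric and the `pairs` metric can rank lists differently;
  cross-study comparisons must fix one.
- Empirical p-values are bounded below by 1/(n_random+1); raising
  `n_random` is the only way to resolve smaller p.
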