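# Methods

## Scope and model

`floraseq` reimplements the downstream, desk-side portion of a sex-biased
floral-organ transcriptome analysis. Everything upstream of the gene-level
count matrix — read cleaning, alignment, counting — is out of scope; the
pipeline starts from a TSV of integer fragment counts with gene lengths and
sample metadata (sex ∈ {female, male, supermale}, organ ∈ {tepal, pistil,
stamen, bud, speartip}, stage, replicate).

### FPKM

FPKM_gs = c_gs · 10⁹ / (L_g · N_s). The library size N_s is the column sum of
the provided counts, which makes the matrix self-contained and exactly
reproducible; when the true mapped-fragment total differs from the counted
total (multi-mapping filters, unassigned reads), a `library_size` metadata
column overrides it. The conservation identity Σ_g FPKM·L·N/10⁹ = Σ_g c holds
to 1e-9 relative tolerance by construction and is asserted on random matrices.

### SDEG rule

Replicate FPKMs are combined by the arithmetic mean per side before testing;
the published criterion does not state its combination rule, and the mean is
the least-structured choice for two replicates (the alternative — requiring
the rule per replicate — is stricter and can be recovered by running each
replicate as its own side). Both inequalities are strict: "higher than 5" and
"more than 5 times higher". A zero on the disfavored side needs no ratio; the
favored side's own floor decides. The two directional sets of a contrast are
provably disjoint for fold thresholds > 1. Jaccard of two empty sets is
defined as 0 to keep heatmaps total.

### One-to-one homology

"Related in a one-to-one manner using the lowest E-values (< 1e-20)" is
implemented as greedy sequential assignment: discard hits at E ≥ 1e-20, sort
by ascending E-value with ties broken by descending bitscore, then query ID,
then subject ID, and accept a hit only when both endpoints are unassigned.
Greedy is the simplest faithful reading; at E < 1e-20 the difference from a
globally optimal bipartite matching is negligible, and the tie-break chain
(invented — the rule needs one to be deterministic) makes the result invariant
to input order. The test suite checks the implementation against an
independently coded replay oracle.

### Enrichment

The sampling of annotated SDEG members from the annotated expressed background
is hypergeometric; the analysis approximates it by a binomial model —
"binomial approximation" — and that binomial model is then computed exactly
via the regularized incomplete beta function (scipy), stable to n ≥ 1e5. For
each annotation type (GO terms, metabolic pathways) a single significance
level α is derived: both one-sided p-values P(X ≤ k) and P(X ≥ k) for every
(set, term) pair are pooled into one family and the Benjamini–Hochberg step-up
critical value at q = 0.01 is taken. Pooling both tails across all sets of one
annotation type mirrors the single published α per analysis; what exact family
the original authors pooled is not recoverable, so the family composition is a
package design choice. Genes in a set lacking any annotation of the type are
excluded from both n and k. Sets with n = 0 emit records called
not_significant, with a logged warning.

### Clustering QC

Correlation is Pearson's r over all genes on raw FPKM. The heatmap view keeps
genes with FPKM > 100 in at least one sample (the published filter does not
say per-sample-maximum or otherwise; any-sample is the inclusive reading),
log10-transforms with pseudocount 1 (FPKM 0 → 0), takes Manhattan distances,
and clusters genes by group-average linkage and samples by Ward linkage.
Ward is applied directly to the Manhattan condensed distances, as R's
`hclust` does with an arbitrary `dist` object; scipy's warning that Ward
assumes Euclidean input is suppressed deliberately. Heatmap coloration uses
per-gene z-scores with the uncorrected (divisor-n) SD; "normalized" is not
further specified in the source, and the z-score is the field's default.
Dendrograms are exported as Newick text with branch lengths splitting each
merge height evenly.

### Summaries

Comparative-Ct relative expression assumes amplification efficiency exactly 2
(perfect doubling), giving 2^−ΔΔCt against an explicit calibrator sample.
`uncorrected_sd` divides by n, not n−1. `integrated_density` is Area × Mean
Gray Value; segmentation that produces the inputs is out of scope.

## Synthetic data

The generator emulates the experimental design: by default 2 sexes × 3 floral
organs × 2 replicates at a postmeiotic stage, plus female/male whole buds at
three stages × 2 replicates (24 samples, 2000 genes). Counts are negative
binomial with variance μ + μ²/θ, θ = 10 by default — a moderate bulk RNA-seq
overdispersion (squared biological CV of 0.1). Expected counts are
proportional to baseline expression × gene length, scaled per sample to a
library size drawn from 0.8–1.2 M fragments; these sizes are chosen for test
speed, not fidelity to any real run, since the source study reports neither
library-size nor dispersion estimates. Baseline expression is log-uniform over
2.5 decades; gene lengths are uniform on 300–5000 bp.

Per sex contrast, 5% of genes receive a multiplicative fold change (uniform
10–50×, above the 5× detection rule) on the biased sex's mean in exactly that
contrast's organ/stage; the biased sex is drawn per gene. 60% of genes get an
injective protein homolog; the hit table contains one true hit per annotated
gene at E ∈ [1e-180, 1e-50] plus Poisson(1.5) decoy hits per gene at
E ∈ [1e-40, 1e-5], so the E-cutoff and ranking are both exercised and the
true map is recoverable by construction. Term catalogs give each protein each
of 100 terms independently at a log-uniform background frequency
(0.01–0.20); three planted terms per contrast are added to that contrast's
biased proteins with probability 0.8.

What the generator does **not** emulate: organ-specific expression programs
(conditions differ only through planted sex-biased genes and noise), GC/length
biases, batch effects, multi-mapping ambiguity, correlated annotation terms
(no GO hierarchy), and paralogy structure in the homology table. Passing
recovery tests therefore shows the pipeline's rules are implemented correctly
and detectable effects are detected — not that the thresholds are optimal for
real tissue.

## Numerical choices

- All rule thresholds are strict inequalities, matching the published wording.
- P(X ≥ k) is computed as 1 − P(X ≤ k−1) with the stable CDF; P(X ≥ 0) = 1.
- BH returns α = 0 when no p-value qualifies; nothing is then significant.
- Agglomeration tie-breaks follow scipy's deterministic nearest-neighbor
  chain; merge heights (the quantity tests assert) are tie-free on continuous
  data.
- The pipeline manifest stores SHA-256 checksums of all inputs and outputs;
  reruns on identical inputs are bit-identical because every stage is
  deterministic given its inputs.

## Problem sizes in tests

The default suite simulates 250–2000 genes × 24 samples per run, 100
simulation replicates for the Ward replicate-pairing rate, 200 null catalogs
for the enrichment false-call rate, 500 random bipartite tables for the
assignment oracle, and 1000 random families for the BH oracle — sizes at which
every targeted effect is already decisively measurable.

## Known limitations

- The published genome-scale figures (SDEG totals, α = 0.00037 / 0.000308,
  ~90% mapping) depend on the original sequence data and are not reproducible
  here; the package reproduces the *procedures* and the two self-contained
  arithmetic checks (38% = 106284/276556, 2% = 5309/276556).
- Greedy assignment is not a maximum-cardinality matching; pathological tie
  structures could assign fewer pairs than an optimal matcher (irrelevant at
  the E-value scales involved).
- Enrichment treats terms as flat labels; no GO-graph propagation.
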