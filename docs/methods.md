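# Methods

This note records the models, statistical procedures, and parameter defaults
implemented in `convreg`, together with the assumptions behind them. Nothing
here is an empirical claim about real genomes; every quantitative statement
about behavior (calibration, power, recovery rates) is computed by the test
suite and by `scripts/acceptance.py` on synthetic data with planted truth.

## Phylogenetic likelihood (`convreg.phylo`)

Nucleotide columns are scored with Felsenstein's pruning algorithm on a rooted
tree with fixed branch lengths (expected substitutions per site). The
substitution model is HKY-style: equilibrium frequencies π and
transition/transversion ratio κ, with the rate matrix normalized to one
expected substitution per unit time at equilibrium. κ = 1 with uniform π
reduces to the Jukes–Cantor model, which has the closed form
P(same base | t) = 1/4 + 3/4·e^(−4t/3) used as an exactness oracle in the
tests. Transition matrices are computed by eigendecomposition of the
symmetrized reversible rate matrix, which is exact for this model class.

Assumptions and choices:

- Gaps and unaligned positions are both treated as fully missing data in
  likelihoods (partial vector of ones). Deletion evidence is handled by a
  separate gap-based caller (below), so gap runs cannot inflate rate
  estimates.
- Branch lengths are inputs, not estimated. The neutral model and neutral
  branch lengths must be supplied (or simulated); the package does not fit
  them from data.
- Per-node rescaling of partial likelihoods keeps the computation stable on
  deep trees (verified to 64 leaves with long branches).
- Likelihood under a reversible model is invariant to root placement and to
  the order of children; both are asserted in the tests.

## Conserved-region calling (`convreg.conservation`)

A two-state phylogenetic hidden Markov model (phastCons-style): a neutral
state emits column likelihoods at scale 1 and a conserved state at scale
ρ < 1 (default 0.3). Posterior probabilities come from the scaled
forward–backward algorithm; Viterbi decoding is also available. Conserved
regions (CRs) are maximal runs with conserved-state posterior above a
threshold (default 0.5), at least 20 bp long, and with at least 50% of
columns informative (some non-missing, non-reference species present).

Transition parameters: the expected neutral segment length sets
μ = 1/45 (probability of leaving the conserved state per bp gives ~45 bp
expected conserved elements) and ν is derived from a prior conserved fraction
of 5%: ν = μ·0.05/0.95, so the chain's stationary conserved probability is
0.05. Both are exposed parameters.

The score threshold controlling the CR false-discovery rate is estimated by
simulation: neutral alignments are simulated under the fitted neutral model,
the same caller is applied, and the threshold is raised until the expected
ratio of null calls to observed calls (rescaled by sequence length) drops
below the target FDR (default 5%).

## Acceleration test (`convreg.acceleration`)

Per CR and per foreground lineage, a likelihood-ratio test (phyloP-style):

- Null: all branches scaled by a conserved scale ρ̂ shared across the tree.
- Alternative: additionally, the foreground terminal branch is scaled by a
  rate multiplier r ≥ 1.

Both ρ and r are profiled in the alternative by coordinate ascent
(golden-section search per coordinate). Pinning ρ at its null estimate is a
known alternative design, but it is slightly anti-conservative-to-conservative
in a length-dependent way and empirically mis-calibrates the type-I rate at
the margins of the nominal level on 40-bp elements; joint profiling restores
calibration (measured by the acceptance suite: empirical rejection at
p < 0.05 within [0.035, 0.065] on 2,000 null CRs).

Because r = 1 sits on the boundary of the parameter space, the null
distribution of the LRT statistic Λ is the mixture 0.5·χ²₀ + 0.5·χ²₁, so
p = 0.5·P(χ²₁ ≥ Λ). The multiplier is capped at r = 1000. CRs with more than
80% gap in the foreground row are reported untestable rather than tested.
Benjamini–Hochberg correction is applied per lineage across all testable CRs
(default FDR 5%); significant CRs are accelerated regions (ARs).

A vectorized batch path evaluates the pruning recursion for thousands of CRs
simultaneously (one matrix-multiply per tree edge across all CRs and
columns); it is asserted to match the scalar path and is used for the
calibration/power experiments.

## Deletion calling (`convreg.acceleration.call_deletions`)

A CR is called deleted in a lineage when the lineage's gap fraction inside
the CR is ≥ 0.8 while both 500-bp flanks are ≥ 50% aligned (so true
alignment absence is distinguished from unalignable regions). CRs whose
flanks are truncated by the alignment edge are flagged. A lineage that is
missing everywhere (flanks included) yields no deletion calls. AR and DEL
calls are mutually exclusive per CR and lineage. The three thresholds are
package choices exposed as parameters.

## Convergence (`convreg.convergence`)

A parallel element is a CR carrying the same event class (AR or DEL) in at
least `min_lineages` (default 2) foreground lineages — identity of the CR,
not mere overlap, is the matching criterion, with CR identifiers shared
across lineages. The excess of parallel elements over chance is assessed by
a bootstrap: in each of B replicates, each lineage's observed number of
calls is redrawn without replacement from the background CR universe, and
the number of parallel elements is recounted. The p-value uses the add-one
rule p = (1 + #{null ≥ observed}) / (B + 1), so it is never zero and its
smallest attainable value is 1/(B+1). Exactness is checked against full
enumeration on a small universe, and calibration under a fully null
generator is checked in the acceptance suite.

## Contact integration (`convreg.contacts`)

Binned chromatin contacts (BEDPE with counts and observed/expected) are
filtered to significant contacts: count ≥ 12, observed/expected > 2, and
BH-adjusted q ≤ 0.01, on 10-kb bins. Promoter bins are those containing any
TSS ± 2 kb. Each element's bin is classified P-P (its own bin is a promoter
bin with a significant promoter contact), E-P (non-promoter bin contacting a
promoter bin, with the contacted genes reported), or no-P; the classes
partition the classifiable elements. Consensus peaks require presence in at
least 4 of 8 replicates (coverage counting on merged intervals) with a
minimum width of 50 bp; species peak sets are partitioned into
species-specific and shared by any-overlap.

## Enrichment statistics (`convreg.stats`)

2×2 tables use the conditional odds ratio with a Wald 95% CI on the log
scale; any zero cell triggers the Haldane–Anscombe +0.5 correction to all
cells (flagged in the result). P-values are two-sided Fisher exact tests
(point-probability method). Heterogeneity of odds ratios across strata uses
the Woolf test: inverse-variance weights w = 1/(1/a+1/b+1/c+1/d) on log odds
ratios, X² = Σ w·(ln OR − pooled)² with k−1 degrees of freedom. Set overlap
uses the hypergeometric upper tail. Multiple testing uses Benjamini–
Hochberg. All four are verified against exact enumeration or independent
closed-form evaluation in the tests.

## Co-expression modules and hubs (`convreg.coexpression`)

A WGCNA-style unsigned weighted network: adjacency |cor|^β with β = 6
(the conventional soft power; configurable), transformed to the topological
overlap matrix TOM = (L + a)/(min(kᵢ,kⱼ) + 1 − a). Modules are flat cuts of
the average-linkage dendrogram on the 1 − TOM dissimilarity, default
cut height 0.9 — on this dissimilarity scale within-module values
concentrate near 0.5–0.7, so a much lower cut would isolate every gene; the
cut height is a parameter. Module eigengenes are the first principal
component of the gene-standardized module submatrix, sign-aligned to the
mean module profile; kME is each gene's correlation with its module
eigengene. Hub genes are the top ceil(10%) of module genes by intramodular
connectivity that also have kME > 0.8 (strict).

## Motif enrichment (`convreg.motifs`)

PWMs are log-odds matrices in bits over a background distribution with a
pseudocount of 0.25 per cell. Scanning slides the PWM over both strands
(reverse-complement hits reported in forward coordinates) and reports
windows scoring at least a fraction (default 0.8) of the maximum attainable
score; windows containing ambiguous bases never match. Group enrichment
compares the per-sequence has-hit counts between query and background sets
with the 2×2 machinery above, BH-corrected across motifs, calling a motif
enriched in one group at q ≤ 0.05. Differences in enriched-motif counts
between conditions use a chi-square test of observed versus expected counts.

## Synthetic data (`convreg.synth`)

All generators take explicit seeds and return machine-readable truth.

- `simulate_alignment`: segments of classes neutral / conserved /
  accelerated / deleted on a fixed 12-leaf tree (4 clades, each with a
  hibernator, a matched control, and a background species). Conserved
  segments scale all branches by ρ; accelerated segments additionally scale
  foreground terminal branches by r; deleted segments blank the deleted
  lineages while leaving flanks aligned.
- `simulate_contacts`: negative-binomial-like counts between bins, with
  element-bin-to-promoter contact probability multiplied by an enrichment
  factor. The truth includes the analytic odds ratio implied by the
  generator, used for CI-coverage checks.
- `simulate_expression`: latent-factor modules, gene = loading·factor +
  Gaussian noise. Loadings are graded so the planted hubs (highest
  loadings) are known. An optional explicit hub tier (`hub_loading`) puts
  the top decile at a fixed high loading: under a pure linear grade the
  per-rank loading gap is far below kME sampling error at realistic sample
  sizes, so no method could identify the exact top-loading set; the tier
  makes planted-hub recovery a well-posed target.
- `simulate_peak_replicates`: per-replicate peak dropout and boundary
  jitter around true peaks.
- `simulate_motif_sequences`: i.i.d. background sequences with one planted
  PWM-consensus instance (random strand and offset) per positive sequence.

Generator realism is deliberately limited: no indel process in alignments
beyond whole-segment deletion, no distance decay in contacts, single-factor
modules, and consensus-exact motif instances. These are the minimal
structures needed to give every estimator a known target.

## Numerical choices

- Golden-section search for one-dimensional likelihood maximization
  (monotone-safe, no derivatives); coordinate ascent for the two-parameter
  alternative.
- Scaled forward–backward and per-node rescaling in pruning to avoid
  underflow.
- Likelihood evaluations are vectorized over CRs and columns with batched
  matrix multiplication.

## Limitations

- HKY/JC only; no rate variation across sites, codon models, or branch-length
  estimation.
- The acceleration test considers terminal branches as foregrounds.
- Flat tree cut instead of dynamic tree cut for module detection.
- The bootstrap convergence null conditions on per-lineage call counts; it
  does not model CR-length or alignability covariates.
- Contact significance assumes the supplied observed/expected values are
  trustworthy; no distance-decay model is fitted.
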