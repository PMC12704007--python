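# Methods

## Drift model and admixture graphs

A `PopulationGraph` is a rooted tree whose non-root nodes carry a drift
parameter `c ≥ 0` (dimensionless), optionally augmented with migration edges
`(source, dest, w)`, `w ∈ (0,1)`, at most one per destination node. Per SNP,
the root frequency `p0` is drawn from a configurable distribution and each
node's frequency is its parent's plus Gaussian noise of variance
`c · p(1−p)` (the parent's heterozygosity), truncated to `[0,1]`. At a
migration destination the mixture `w·f(source) + (1−w)·f(tree parent)` forms
first; the destination branch's own drift is then applied to the mixed
lineage. Migration sources created by the edge search sit at the midpoint of
the donor branch (the donor's drift is split in half), which bounds the
search space; refining the attachment position is out of scope.

The model covariance follows from ancestry coefficients: writing
`f(leaf) − p0 = Σ_b a(b)·e_b` over branch noise terms, with
`a(dest) = w·a(source) + (1−w)·a(parent) + 1_dest`, the covariance in drift
units is `W = U diag(v) Uᵀ`. Two variants of the per-branch variance `v` are
available:

* **raw** (`het_decay=False`, default): `v_b = c_b`. This is the linear form
  used in fitting — the model is then linear in the drift parameters, so
  non-negative least squares applies.
* **exact** (`het_decay=True`): because drift noise is scaled by the
  *parent's* realized heterozygosity, `E[p(1−p)]` decays along the tree;
  exactly, `v_b = c_b (1 − V_parent)` where `V_parent` is the parent's
  accumulated variance coefficient (computable in topological order, and for
  mixtures from the joint coefficients). This form is used wherever the
  simulator is compared against the model at Monte-Carlo precision; at
  typical drift values the difference is second order, but it exceeds
  block-resampling standard errors at 5×10⁴ SNPs.

Truncation at the frequency boundaries is the one effect the covariance
algebra ignores. The simulator/model consistency check therefore runs in a
truncation-free regime — per-branch drift 0.02 and root frequencies uniform
on (0.35, 0.65), giving boundary mass below 0.2% — and compares the
*unnormalized* sample covariance against `E[p0(1−p0)] · P W P` (centering
projection `P = I − 11ᵀ/n`). The default covariance estimator instead
divides each SNP's centered cross-products by the across-population mean
heterozygosity (drift units, the convention for fitting); that ratio carries
a small multiplicative bias of order the mean drift which is unidentifiable
from centered data, which is why the consistency check uses absolute units.

## Covariance estimation

`block_covariance` centers each SNP by the across-population mean (removing
ancestral-frequency variance), optionally normalizes by mean heterozygosity,
and averages per-block covariance matrices over consecutive blocks of 100
SNPs within chromosomes (trailing partial blocks dropped; missing entries
pairwise-complete). The standard error of each entry is the standard error
of the block means. Block size preserves local linkage structure in the
uncertainty estimate; 100 SNPs is the default throughout.

## Graph fitting and PCVE

Fitting compares centered matrices on both sides, since the sample
covariance is only defined up to centering. The start tree is neighbor
joining (scikit-bio) on the covariance-implied distances
`d_ij = W_ii + W_jj − 2W_ij` (which are centering-invariant), rooted on the
outgroup; branch drift comes from non-negative least squares over all unique
entries including the diagonal. With migration edges the fit alternates
exact NNLS for drift with a bounded scalar search for each weight
(convergence when the objective improves by < 1e−10, cap 500 iterations;
weights live in [1e−4, 1−1e−4], so a useless edge shrinks to the boundary
where the model nests the pure tree). The greedy nested search enumerates
candidate (donor branch, destination node) pairs in deterministic
lexicographic order, screens them with a two-iteration fit, refines the best
three fully, and seeds each edge count with the best graph at the previous
count; restarts perturb the start topology by k ~ 1 + Poisson(1) random NNI
moves. Individual drift values are identified only up to the centering
projection; the fitted covariance and migration weights are the meaningful
outputs.

**PCVE** is `1 − SS_res/SS_tot` over unique *off-diagonal* entries, `SS_tot`
taken around the grand mean of the observed entries, clipped to `[0,1]`.
The diagonal is excluded by default because per-population drift variance is
exactly representable by pendant branches of any tree: including it
(available via `include_diagonal=True`) saturates the statistic at small
population numbers — exhaustive-topology fits to exact one-edge model
covariances show the best bifurcating tree then always explains ≥ 97%
regardless of how strongly the graph violates tree constraints, masking the
between-population structure the statistic is meant to expose. The fitting
objective itself still uses all unique entries including the diagonal.

## Coded alleles, chromosome trees, tree distances

Within a population a SNP is coded ALT when its frequency is ≥ 0.95, REF
when ≤ 0.05, else ambiguous `N` (threshold configurable; the comparison is
`≥`). Chromosome trees use neighbor joining on pairwise Hamming distances
(proportion of sites with different non-`N` codes, pairwise-complete),
rooted on the outgroup; estimation is refused below a per-pair floor of 100
jointly informative SNPs (configurable). Only topology is retained.

The generalized Robinson–Foulds distance between two topologies is the
clustering-information form: each nontrivial split is a two-class clustering
with entropy `H(|A|/n)` bits; splits of the two trees are matched one-to-one
by maximum-weight bipartite assignment on pairwise mutual clustering
information; distance = total split entropy − 2 × matched information. It is
zero exactly when the split sets coincide, and is verified in the tests
against brute-force enumeration of all matchings on 6-leaf trees. The plain
Robinson–Foulds count (splits in exactly one tree) is provided as a
cross-check metric.

The heterogeneity test permutes the SNP-to-chromosome assignment (preserving
per-chromosome SNP counts, asserted on every draw), re-estimates every
chromosome tree per permutation, and reports
`P = (1 + #{null ≥ observed}) / (1 + n_permutations)` with 50 permutations
by default — so P is never 0 and the smallest attainable value is
1/51 ≈ 0.0196. Draws that push a chromosome below the SNP floor are redrawn
and counted.

## Quartet scores

A site votes when all four taxa are unambiguous and exactly two of the three
focal populations carry the allele differing from the outgroup; the vote
goes to the topology grouping those two. Votes are counted in disjoint
10-kb base windows anchored at position 1 of each chromosome, vote *counts*
are averaged across the base windows of each 50-kb sliding window (step
10 kb; base window must divide both), and the averages normalized to sum to
one; windows without votes are reported missing. Averaging counts (not
per-base-window normalized scores) weights base windows by their
information; the alternative is a one-line change. Window coordinates are
1-based inclusive in outputs. Score summaries use the population variance
convention (divide by n) for both the within-chromosome variance of window
scores and the among-chromosome variance of mean scores. Correlations with
chromosome size are Pearson, with Fisher-z intervals and t-test P-values.

## Bayesian size regression

PCVE-on-size regression standardizes both variables and uses the conjugate
normal-inverse-gamma posterior: coefficients `N(0, σ²)` a priori
(`prior_scale=1`, i.e. a standard-normal slope prior on the standardized
scale), `σ² ~ Inv-Gamma(2, 1)` (prior mean 1, matching standardized data).
The slope's posterior is a scaled t; the summary reports its mean, 95%
equal-tail interval, P(slope < 0), and the ordinary least-squares R².
No sampler is involved; conjugacy is verified by sequential-update tests.
A constant response yields a posterior centered at zero (P(slope<0) = 0.5)
and is flagged; a constant predictor is an error.

## Effects and Va partitioning

The bundled effect estimator is ridge regression on centered genotypes with
the penalty chosen by generalized cross-validation
(`GCV(λ) = n·RSS/(n − df)²`, `df = Σ d²/(d²+λ)`, log-spaced grid anchored at
the squared singular values); `λ = 0` is refused when p ≥ n. The partition
`Va_c = Σ 2p(1−p)β²` ignores linkage cross-terms, matching a computation
from effects and frequencies alone; `empirical_partition_va` computes
per-chromosome variances of realized genetic values instead (within-
chromosome linkage included). Allele frequencies come from the mapping
sample. The two agree exactly for orthogonal genotype columns.

## Synthetic study conditions

The generator's canonical scenarios live in `treemosaic.scenarios`:

* Root frequency spectra: uniform(0.05, 0.95) as a generic default;
  beta(0.5, 0.5) (U-shaped, neutral-like) wherever coded alleles are the
  input, because the 0.95 rule needs near-fixed sites; uniform(0.35, 0.65)
  for model-consistency checks (truncation-free).
* Drift regimes: 0.02 per branch for model checks; 0.25 for coded-allele
  tree studies — the value at which the Hamming/NJ estimator recovers the
  generating six-population topology essentially always at 5000 SNPs
  (at 0.1 recovery is ~20%, drowning topology signal in estimator noise);
  ~0.3–0.8 for quartet scans, where votes require independent lineage
  fixation.
* The migration-recovery scenario places strong drift on the donor lineage
  and the recipient's parent branch, the configuration a bifurcating tree
  demonstrably cannot absorb; true weight 0.4.
* The genome-scale study (`study_genome_config`): 22 autosomes (24 Mb down
  to 8 Mb) plus a Z at 5.5% of the genome; autosomes carry one edge with
  weight increasing in size from 0.15 to 0.45, the Z none; ~1 SNP / 2 kb;
  pool-seq at mean depth 60 with pools of 48 diploids (pool depths are free
  parameters here — no empirical values are available to emulate).
* Pool-seq: allele count `Binomial(2N, p)` then reads
  `Binomial(Poisson(depth), k/2N)`; zero-depth sites are missing.
* Trait data: Hardy–Weinberg 0/1/2 genotypes, standard-normal effects on a
  random (or caller-specified) causal set, noise scaled to the target h².

Problem sizes in the validation studies (5×10⁴ SNPs for covariance checks,
2×10³ SNPs per chromosome × 50 replicates for the tree-likeness contrast,
200 replicate genomes for permutation calibration, 50 replicates for score
symmetry) were chosen as the smallest at which Monte-Carlo error is clearly
below the effects being tested.

What the generator does *not* emulate: linkage (SNPs are independent given
the graph, so block-resampling SEs on synthetic data are if anything
conservative relative to real linked data), coalescent gene-tree
discordance (quartet discordance arises only from drift-fixation and
admixture), selection, mutation, reference bias, and pool-construction
artifacts. Passing tests demonstrate internal consistency of model,
estimators and tests under the stated drift model — not robustness to those
real-data features.

## Numerical choices and degenerate inputs

* Tie-breaks in the edge search are deterministic (lexicographic); a single
  integer seed drives all randomness through `SeedSequence` spawning.
* PCVE with a constant observed covariance (zero `SS_tot` to numerical
  tolerance) is an error, as are correlations of zero-variance variables,
  all-zero effect vectors, and coding thresholds ≤ 0.5.
* Identical coded columns give zero Hamming distance and come out as
  siblings; permutation P-values are exact over their attainable grid.
* The entry-wise covariance consistency test uses a Šidák-corrected
  two-sided bound (familywise 0.05 over the 15 unique entries) — the
  per-entry two-standard-error check made multiplicity-aware.

## Known limitations

* The tree/graph fit is least squares, not the composite Gaussian
  likelihood; standard errors on migration weights are not produced.
  Optional SE-weighting of residuals is available.
* One incoming migration edge per node; migration sources at donor-branch
  midpoints only.
* The coded-allele chromosome-tree estimator is a deliberately simple,
  fully specified stand-in for site-pattern quartet amalgamation methods;
  the permutation machinery accepts any estimator with the same signature.
* The ridge/GCV effect estimator replaces Bayesian sparse mixed models; the
  partition formula is estimator-agnostic and accepts external effects.
* At few populations the covariance of a one-edge graph is close to some
  tree's, so PCVE contrasts need the strong-violation configurations above;
  with ~20 populations (as in real data) non-tree structure is far easier
  to expose.
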