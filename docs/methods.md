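# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not establish.

## Differential expression

Expression arrives as gene-level expected counts and is analysed on the
log2(count + 1) scale; the scale tag on the matrix makes a double
transform a hard error.  The test is a per-gene Welch two-sample t
(unequal variances) with Benjamini–Hochberg correction over all tested
genes and the conventional dual threshold (adjusted p ≤ 0.05,
|log2FC| ≥ 1, both configurable).  This is a transparent substitute for
moderated-t pipelines: the contrast and the decision boundary are the
same, and no variance-shrinkage hyperparameters are introduced.  With
tens of samples per group — the regime of every cohort here — variance
moderation changes little; with very few samples per group the Welch test
is conservative, which is the main caveat for transferring results to
small real cohorts.  No library-size normalization is applied by default
(gene-level expected counts); `upper_quartile_normalize` is available when
counts need it.  Genes with zero variance in both groups get p = 1 when
the group means coincide and p = 0 when they differ exactly.

## Network construction

Pairwise Pearson correlations are computed over the **tumour cohort only**.
This matters: pooling tumour and normal samples lets the differential mean
shifts act as a shared factor, so any two shifted genes correlate
regardless of regulatory relationship — observed directly on synthetic
cohorts, where pooled-sample networks acquire spurious edges between
independent genes.  Edge p-values use the exact null transform
t = r·√((n−2)/(1−r²)) with n−2 df; BH runs over the full family of tested
pairs (the family is all pairs tested in that cancer type).  Pairs passing
adjusted p ≤ 0.05 are intersected with the interaction database; any pair
present in the supplied table counts (no score threshold).  Genes with
zero variance are excluded with a logged count; isolated candidates are
dropped, so the node set is the endpoints of surviving edges.

Correlation edges are undirected, but the controllability theory operates
on directed graphs.  Each kept pair becomes an antiparallel pair of
directed edges with shared attributes — the symmetric, assumption-free
choice.  Users with genuinely directed regulatory input can build networks
with `convention="as_given"`.

## Controllability

The minimum driver node set (MDNS) size of a directed network on N nodes
is max(N − |M*|, 1), where M* is a maximum matching of the bipartite lift
(out-copy of u joined to in-copy of v for every edge u→v); unmatched
in-copies witness one driver set, and the floor of 1 covers the perfectly
matched case, which still needs one control input.  Matching uses
Hopcroft–Karp over lexicographically sorted out-copies; the cardinality —
the only quantity MDNS and criticality depend on — is order-invariant,
so the classification is deterministic under any edge ordering, even
though the witness driver set is not unique.

A node is critical iff deleting it (with incident edges) strictly
increases the MDNS of the remaining network, evaluated globally (not per
component) against the intact network's MDNS.  Single deletion changes
the matching by at most two and N by one, so the MDNS moves by at most one
in either direction; the suite asserts this on random graphs and checks
exact agreement of MDNS and critical sets with an exhaustive
matching-enumeration oracle on 200 random digraphs of up to 8 nodes.

## Survival stratification

Univariate Cox fits use the standard partial likelihood with a Wald test;
a constant covariate returns hazard ratio 1, p = 1 by convention.  The
direction of a candidate gene is a strict majority vote of its significant
up/down DE calls across the cancer types in which it is critical;
non-significant calls abstain and ties leave the gene unclassified, which
drops it from directional signatures.

Spectral stratification follows the similarity-network-fusion
construction: squared Euclidean distances between patients' signature
vectors; a locally scaled Gaussian-density kernel with neighbourhood size
K = 20 and scale μ = 0.5 (both exposed; the values are the named
toolkit's defaults, since no others are specified); normalized-Laplacian
spectral clustering with seeded k-means assignment.  Note that clusters
follow overall geometry, not hazard direction: a signature mixing harmful
and protective genes can cluster cleanly yet show no survival difference.
That observation motivates the second stratification mode, the median
rule: each gene dichotomized at the cohort median (ties to low —
deterministic and conservative toward the reference group), subtype 2 the
exact good-prognosis pattern (high on every tumour-down gene, low on every
tumour-up gene), subtype 1 the exact mirror, subtype 3 everything else.
Up- and down-signatures can also be run separately and combined.

Log-rank comparisons use the k-group statistic with k−1 df (three groups
whenever subtype 3 is non-empty, pairwise 1-vs-2 available), with
Kaplan–Meier curves and at-risk counts per group.  The implementation is
checked against the textbook O−E hand computation and the closed-form
product-limit on small examples.

## Mutation analysis

Pathogenic SNVs satisfy all of: deleterious classification (missense,
nonsense, frame-shift ins/del, splice site, in-frame ins/del); VAF
computed exactly as t_alt_count / t_depth strictly greater than 0.1;
FILTER == PASS; REVEL category in a pathogenic band.  The REVEL cut-points
(supporting/moderate/strong pathogenic at 0.644 / 0.773 / 0.932;
benign at 0.290 / 0.183 / 0.016; boundary scores route to the stronger
band, middle band non-pathogenic) follow published clinical-calibration
thresholds and are deliberately configurable — they are a calibration
choice, not a property of the data, and should be revisited per cohort.
Calls without a REVEL annotation are non-pathogenic.  Mutant status per
(gene, sample) is pathogenic SNV OR homozygous deletion/amplification;
heterozygous events never count; multiple hits count once.  Pooled status
is mutant for ≥1 tested gene, and survival contrasts reuse the log-rank
machinery pooled and per gene.

## Risk model

Candidates pass a univariate Cox screen (p ≤ 0.05), then an L1-penalized
Cox fit runs over 100 log-spaced λ values from λ_max (smallest penalty
zeroing all coefficients) down to 0.001·λ_max.  Expression is z-scored per
gene on the training cohort (penalty fairness across genes); the stored
means/sds transform validation cohorts.  Ten-fold cross-validation with
seeded fold assignment scores each λ by the Verweij–van Houwelingen
partial-likelihood deviance, D_k(λ) = −2·(ll_all(β_k) − ll_train(β_k))
with Breslow tie handling.  The selected λ uses the one-standard-error
rule: the largest λ whose mean deviance is within one SE of the minimum.
The plain argmin is available (`rule="min"`) but not the default: the
deviance curve is characteristically flat near its minimum, and argmin
routinely drags in noise genes with near-zero coefficients, defeating the
selection purpose; the 1-SE rule is the standard remedy in the penalized
regression literature and recovers planted 6-of-10 models with no false
positives in the benchmarks.  Validation computes risk scores with frozen
coefficients (no refit) and IPCW cumulative-case/dynamic-control AUC at
requested horizons, with censoring weights from the training cohort's
Kaplan–Meier censoring distribution; horizons outside the evaluable
follow-up window return NaN with a warning.

## Synthetic cohorts

The generator plants every structure the pipeline is supposed to find.
Latent log2 deviations follow a linear structural-equation model over a
planted DAG (cycles rejected — DAGs sample exactly in one topological
pass and induce the needed correlation structure); observed log2
expression is a per-gene baseline (Uniform(6, 10), keeping the count
back-transform 2^x − 1 away from truncation at zero) plus the latent value
plus a ±2 log2 tumour shift for DE genes; noise sd defaults to 0.5.
Survival is exponential proportional hazards, h = λ₀·exp(Σ β_g z_g) with
λ₀ = 0.001/day on z-scored expression, censored Uniform(0, 3000 days) —
roughly 30% censoring at null effects.  Mutation tables mix planted
pathogenic calls (always filter-compliant, REVEL ≥ 0.95) with decoys each
violating exactly one filter rule, plus homozygous and heterozygous CNV
events; pooled mutant status can feed a log-hazard increment (default 0.7)
back into survival.

The reference configuration (`default_cohort_config`) uses 150 genes, 550
tumour / 200 normal samples, three 6-gene stars and three 6-gene chains
with weight 0.9, ±2 shifts on all 36 network genes and 20 independent
genes, six prognostic critical genes at β = ±0.8 placed one per network
component — deliberately, so correlated neighbours with opposite hazards
cannot cancel in the marginal Cox screen — and four independent genes
forming a 2-up/2-down subtype rule (a 5+3 rule would leave the exact
pattern subtypes nearly empty at this cohort size, since the extreme
patterns occur at rate 2^−k for k independent genes).

Ground-truth critical nodes are defined by running the control module on
the antiparallel symmetrization of the planted DAG — the graph the network
stage reconstructs under its own edge convention given perfect edge
recovery — so end-to-end recall measures the pipeline, not a convention
mismatch.  Under symmetrization, star hubs and all genes of even-length
chains are critical (removing any chain gene destroys the chain's perfect
matching), star leaves are not.

What passing these benchmarks shows: the chain of estimators recovers the
structure it assumes, at realistic cohort sizes, under correctly specified
noise.  What it does not show: robustness to the features of real cohorts
the generator omits — batch effects, library-size artifacts, heavy-tailed
and zero-inflated counts, cyclic and condition-specific regulation,
non-proportional hazards, informative censoring, and interaction databases
whose coverage is biased rather than merely incomplete.

## Problem sizes in the shipped benchmarks

The test suite and the acceptance script run the stages at the sizes the
properties are stated for: 200 random graphs (N ≤ 8) against the
enumeration oracle; 20 replicates of 2 000 genes (200 shifted) for DE
recall/FDR; n = 2000 for Cox recovery and 50 null replicates of n = 1000
for its type-I rate; 20 replicates of n = 400 for log-rank power; 10
replicates each for spectral ARI and lasso recovery (n = 500); 20 null
replicates of n = 1000 for AUC; five cohorts of 550 + 200 samples end to
end.  The full suite completes in well under a minute of CPU.
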