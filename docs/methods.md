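# Methods

This note documents the statistical procedures `exponet` implements, the
defaults it ships, the design choices made where the design was open,
and what the synthetic studies do and do not demonstrate.

## Data model and preprocessing

Each omic layer is a features × samples abundance matrix with optional
per-sample collection windows (ISO dates). All abundances are
log2(x + pseudocount)-transformed before correlation analysis; the
pseudocount defaults to 1.0 and only shifts values, never reorders them,
so downstream Spearman statistics are invariant to it on complete data.

*Prevalence filter.* A feature is kept when its observed fraction is
**strictly greater** than the threshold (default ⅓). The strictness
matters at the boundary: 6/18 observed is dropped, 7/18 kept.

*KNN imputation* (default k = 5) is feature-wise: a missing cell
(feature f, sample s) becomes the mean over the k features nearest to f
in Euclidean distance on their shared observed samples — the classic
expression-matrix scheme, delegated to scikit-learn's `KNNImputer`
applied to the features-as-rows orientation. Features with no observed
value are an error, as is k exceeding the available neighbours.

*Covariate residualization.* Known interventions (here two dietary
fiber periods: arabinoxylan 2016-01-15..01-31, guar gum
2016-02-22..03-17, encoded as binary window-overlap indicators) are
removed per feature by OLS. Covariates are centered before fitting, so
the intercept equals the feature mean and the returned matrix is
residuals + mean: feature means are preserved exactly, the operation is
idempotent to 1e-10, and an all-zero covariate table reduces to the
identity (zero-variance covariate columns are dropped rather than
treated as a rank defect, since they carry no information beyond the
intercept). Whether such adjustments are best done by residualization
or by carrying covariates into downstream models is a modelling choice;
residualization is the default here and the covariate table is exposed
so users can switch.

*Window alignment.* Because each ome is collected on its own calendar,
two blocks are paired sample-to-sample before correlation: candidate
pairs overlap by ≥ 1 day or lie within a gap tolerance (default 2 days,
matching 1–3 day collection windows), and a greedy matching ordered by
(overlap desc, gap asc, earliest start) yields a deterministic
one-to-one map.

## Correlation networks

Spearman's ρ is the Pearson correlation of midranks, with pairwise
deletion of missing values and a minimum of 5 complete pairs (constant
vectors are skipped and logged). Two-sided p-values use the
t-approximation with n−2 degrees of freedom, which matches common
implementations at the study's n ≈ 9–18; an exact permutation option
was considered and rejected as unnecessary given that edges are
thresholded primarily on |ρ|.

Benjamini–Hochberg adjustment is applied across **all tests of one
block-pair analysis** (`fdr_scope="pair"`). The alternative readings —
adjusting within each source feature's family (`per_variable`) or
pooling every analysed pair (`global`) — are implemented as switches,
because published edge counts can depend on this choice and the
convention is often unstated. Edges survive at |ρ| > r_min and
q < q_max, both strict; the study thresholds are 0.9 and 0.05.

## Community analysis

Girvan–Newman with deterministic bookkeeping: one edge removed per
iteration (the highest unweighted edge-betweenness; ties broken
lexicographically), betweenness recomputed after every removal, and the
Newman–Girvan modularity of the current connected-component partition
evaluated **on the original graph** (m fixed to the original edge
count) so Q values along the trace are comparable. The partition
maximizing Q is returned together with the full trace. Correlation
magnitudes are discarded — the algorithm runs on the unweighted graph
of significant edges. Communities with fewer than 3 nodes are filtered
after the best partition is chosen. Edge betweenness itself is
delegated to networkx; the test suite checks it against an exact
all-pairs rational enumeration on small random graphs.

## Dysregulated metabolic modules

*Adduct matching.* A feature (m/z, polarity) matches metabolite mass M
under adduct (shift s, charge z) when |mz − (M+s)/|z|| relative to
(M+s)/|z| is within the ppm tolerance (default 10 ppm — a typical
high-resolution Orbitrap figure; the tolerance is exposed). The bundled
default adduct table covers [M+H]+, [M+Na]+, [M+NH4]+, [M−H]−,
[M+CH3COO]− and [M+Cl]−.

*Subnetwork.* The matched (significant) metabolites plus every hidden
metabolite lying on a path of ≤ 3 reactions between two distinct
significant metabolites (both legs ≥ 1; evaluated via truncated BFS
distances) with induced edges. The hidden set is monotone in the step
limit.

*Modules.* Walktrap random-walk clustering with walk length t = 4 via
igraph, cut at maximal standard modularity, run per connected component
for locality; the walk distances are computed exactly so the procedure
is deterministic. Modules need ≥ 3 nodes.

*Activity score.* For module M, with m and degrees k from the **full**
network: Q_adj = (N_I/N_M)·(E_M/m − Σ_{i<j∈M} (k_i/2m)(k_j/2m)) and
S = Q_adj·N_I,M/N_M. The N_I/N_M factor counteracts the large-module
bias of raw modularity. Two interpretive choices are exposed as
switches because the index notation of such sums is conventionally
ambiguous: the pair sum runs over unordered distinct pairs by default
(`pair_convention`), and N_I is the total matched input count rather
than the in-module count (switchable). Negative scores are floored at
0 before null modeling.

*Null and p-values.* 100 resamples draw |significant| features
uniformly without replacement from the non-significant pool and run the
identical pipeline; the pooled positive null scores (pooling across
resamples, rather than per-resample summaries, keeps the tail sample
size reasonable) are fitted with a Gamma(shape, scale) by maximum
likelihood (location 0; zeros excluded, since Gamma support is
positive). Module p = 1 − GammaCDF(S); modules with p < 0.05 are kept.
Fewer than 30 pooled scores or degenerate (all-equal) scores abort with
advice rather than producing a meaningless fit.

## Pathway enrichment

Upper-tail hypergeometric p = P(X ≥ k) for k hits among n selected from
a universe of N containing K pathway members, computed through scipy's
log-stable survival function and verified against exact rational
combinatorics. The universe is the set of measured features of the
relevant ome (not the union of pathway members) — a deliberate choice
that keeps the background honest when coverage is partial; pathways are
intersected with the universe before counting and disjoint ones are
skipped. BH runs across tested pathways; protein mode additionally
requires hits strictly greater than 3 (applied post-test), metabolite
mode defaults to no hit filter.

## Exposome contributions

Per category (chemical / biological / environmental), the features
linked to the outcome in the correlation network (or all features, via
`feature_mode="all"`) are z-scored — exposome units are heterogeneous —
and PCA-reduced, keeping the smallest leading component set whose
cumulative explained variance strictly exceeds 80%, with a
deterministic sign convention (largest-magnitude loading positive).
The pooled component scores predict the outcome by OLS (R²; an error is
raised when predictors reach the sample count, with an explicit ridge
fallback flag). A single-response PLS (scikit-learn NIPALS, component
count = kept PCs capped at min(5, n−2)) yields
VIP_j = sqrt(p·Σ_a SS_a (w_ja/||w_a||)² / Σ_a SS_a), whose mean square
is identically 1. Category shares R²·ΣVIP_c/ΣVIP sum to R² exactly
(asserted to 1e-10). Across outcomes, both the plain mean R² and the
variance-weighted mean are reported and labelled, since "overall
explained variation" admits either aggregation.

## Synthetic studies

The generators are pure functions of (spec, seed).

* **Correlation study** (default spec): two 40-feature blocks over 18
  consecutive 1–3-day collection windows starting 2016-01-15; 20
  planted pairs at population Spearman 0.97 via a Gaussian copula on
  ranks (latent correlation 2·sin(π·ρ_S/6)), leaving 400 null–null
  pairs; backgrounds are i.i.d. log-normal, abundance-like so the log2
  stage is exercised. At these conditions ~94% of planted pairs survive
  the |ρ| > 0.9, Q < 0.05 thresholds (a population ρ of 0.97 at n = 18
  leaves real sampling noise), and the surviving edge set equals an
  independent per-pair recomputation exactly.
* **Metabolic study**: 60 metabolites, Erdős–Rényi background at edge
  probability 0.05, one planted 8-node module at density 1.0, masses on
  a 0.05 Da grid in 80–600 Da so each simulated [M+H]+ ion matches
  exactly one metabolite at 10 ppm; 40 decoy ions. The planted module
  is recovered at p < 0.05 in ≥ 90% of seeds; with uniformly drawn
  decoy "significant" sets, the fraction of null modules called at
  α = 0.05 sits within binomial error of α (the decoy draws are
  exchangeable with the null resamples, so a shared Gamma null is
  valid). The type-I calibration is evaluated per module; a per-run
  "any module significant" rate is family-wise inflated by the several
  modules each run yields and is not the calibrated quantity.
* **Contribution study**: three 20-feature category blocks whose
  features co-load (loading 0.9) on a latent category driver — a strong
  shared seasonal/behavioural factor, which also keeps the kept-PC
  count near 1 per category so OLS at n = 18 is identified — and
  outcomes y = 0.8·PC1(chemical) + ε with noise calibrated to
  population R² = 0.6. Estimated R² averages ≈ 0.66 (OLS overfit at
  n = 18 with 3–5 predictors biases upward); the dominant category is
  ranked first in ≥ 90% of seeds.

What the synthetic studies do **not** emulate: real chemical classes or
taxonomies, KEGG topology statistics, autocorrelated time dynamics,
batch effects, or the heavy ties and censoring of real measurements.
Passing recovery tests therefore demonstrates correctness of the
machinery under the stated generative assumptions, not field
performance on real studies.

## Numerical and scale choices

Problem sizes were chosen so the full suite runs in well under a minute
and the acceptance script in seconds: 1,000-pair kernel sweeps, 12-node
exact-enumeration graphs, 20-seed module recovery, 50-seed contribution
recovery. BH uses a stable mergesort; all tie-breaks (edge removal,
module ordering, degree tables, alignment) are lexicographic and
documented at the function level, making every pipeline stage
deterministic at fixed seed. Reproducing the original study's absolute
network sizes (thousands of edges across eight omes) requires its
deposited matrices; all readers, thresholds and FDR-scope switches
needed to consume them are present.
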