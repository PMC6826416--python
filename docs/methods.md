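# Methods

## Ground-truth model and synthetic data

The generator (`ednet.datasets`) emulates a clinical sample of 84 anorexia
nervosa patients assessed with 4 IDEA embodiment subscales and 11 EDI-2
subscales. A ground-truth Gaussian graphical model is built from an edge
list of partial correlations: with a constant precision diagonal `d`, setting
`K_ij = -r_ij * d` makes the implied partial correlation exactly `r_ij`, so
the published edge values are reproduced without error whenever the
resulting matrix is positive-definite. The reference model uses the eight
strongest published edges (OM–S 0.42, SI–IN 0.44, OM–DT 0.31, EB–S 0.29,
IA–I 0.26, IA–ID 0.24, IA–EB 0.24, EB–I 0.13) on `d = 1`; that matrix is
comfortably positive-definite (smallest eigenvalue ≈ 0.21), so no repair is
involved.

When an arbitrary edge list is *not* positive-definite, the matrix is
repaired by adding `tau * I`. Because eigenvalues shift exactly by `tau`,
the smallest shift reaching a minimum eigenvalue of 1e-3 is the closed form
`tau = 1e-3 - lambda_min`; no search is needed. The repair is transparent:
the model records both the requested and the achieved partials.

Subjects are drawn multivariate-normal from the correlation matrix implied
by `K` (partial correlations are invariant to marginal rescaling) and then
rescaled to the published subscale means and SDs; scores are continuous, as
the analysed subscale totals are treated as continuous. An optional
clip-to-range emulates floor/ceiling effects. Group labels follow the
published 57:27 restricting to binge-purging split, and the BU (bulimia)
column is rescaled per group to the published group marginals
(1.30 ± 2.38 vs 7.35 ± 6.51) so the one real subtype difference is present.

What the generator does **not** emulate: item-level (ordinal) response
processes, skewed or floor-heavy marginals, missing data, and — importantly
— the dense web of weak conditional associations that real questionnaire
data carry beyond a handful of printed edges. Consequences are visible and
intended: at n = 84 the EBIC(0.5) selection on this sparse truth is empty or
near-empty, whereas the original clinical analysis at the same n produced a
connected network. Passing tests therefore certify the machinery (recovery,
calibration, stability behaviour) against a known truth, not that real data
of this size would yield a rich network.

## Network estimation

Pearson product-moment correlations on subscale totals feed the graphical
lasso (correlation type pluggable in principle; ordinal/polychoric variants
are out of scope). The solver (`ednet._glasso`) is the classic block
coordinate-descent algorithm: each column update solves an L1 regression on
the current covariance estimate by cyclic coordinate descent with soft
thresholding. The penalty path is 100 log-spaced values descending from
`lambda_max = max|S_ij|` to `lambda_max / 100`, warm-started along the path.
The precision diagonal is unpenalized (penalizing it deflates all partials).
Convergence is declared when the largest covariance update falls below
`solver_tol` (default 1e-7); non-convergence raises an error carrying the
convex duality gap. The solution agrees with scikit-learn's
GraphicalLasso (LARS mode, tight tolerance) to ~1e-11 per entry in the
cross-check test.

Edge counting for the EBIC uses the *exact* zeros the lasso produces — the
zero pattern is tracked in the regression coefficients, so no numerical
epsilon is involved. EBIC ties are broken toward the larger penalty
(sparser model). Sample-size guards: estimation requires `n >= p + 1` and
warns below `3p`.

## Centrality

Strength is the sum of absolute incident weights; negative edges contribute
their magnitude. Closeness follows the inverse-total-distance convention
`c_i = 1 / sum_j d(i, j)` with edge length `1/|w|`; on disconnected graphs
the sum runs over the reachable component and the node is flagged (an
isolated node has closeness 0). Betweenness counts shortest paths between
unordered pairs through the node, with fractional credit under ties.
Z-standardized columns (mean 0, SD 1 across nodes, SD with `ddof = 1`) are
emitted alongside raw values because centrality plots are conventionally
drawn on either scale. Shortest paths and betweenness are delegated to
networkx (Dijkstra); tests verify them against exhaustive simple-path
enumeration on all graphs up to 6 nodes.

## Bootstrap accuracy and stability

Edge accuracy: subjects are resampled with replacement (default 2500
replicates; 500 in the quickstart profile) and the **full** estimator —
correlation, path, EBIC selection — is re-run per replicate; per-edge 95%
intervals are the 2.5%/97.5% quantiles of the replicate weights. Replicates
drawing a zero-variance column are redrawn (logged, capped).

A caveat the package surfaces deliberately: percentile CIs of
lasso-regularized edges are *not* calibrated confidence intervals for the
true weight whenever the selected penalty is non-negligible, because the
lasso biases estimates toward zero while the interval tracks only sampling
spread. Probing this across designs (3–15 nodes, n = 75–1000, gamma 0 and
0.5) gave true-weight coverage from ~20% (15 nodes, n = 1000, where bias is
several times the SE) up to ~95% where the selected penalty is near zero.
The coverage test therefore uses a small dense graph (3-node chain, partials
0.45, n = 600, 200 bootstrap replicates, 200 datasets) where the estimator
is essentially unbiased and nominal coverage is actually attainable; the
undercoverage elsewhere is a property of the method, not of this
implementation (the solver is cross-checked independently).

Stability: for each drop proportion `q` in {0.05, 0.15, ..., 0.75} (grid
configurable), subsamples of size `round(n (1 - q))` are drawn without
replacement (floor `p + 2` subjects), the network and centralities are
recomputed, and each index vector is Pearson-correlated with the full-sample
one (Spearman available). Replicates with a degenerate centrality vector —
typically an empty selected network — are recorded as correlation 0 and
counted, not dropped, since dropping them would inflate apparent stability.
The CS coefficient is the largest grid proportion such that at it, and at
every smaller proportion, at least 95% of replicates correlate ≥ 0.7
(threshold and quantile exposed). CS is reported **on the grid**; no
interpolation between grid points is performed, so values are conservative
relative to software that interpolates.

## Group comparison

Welch's t-test is the default (group sizes 57 vs 27 with visibly unequal
variances); Student's pooled variant is available, and for the decisive BU
contrast both give p < 0.001. The Bonferroni family size is the number of
variables actually tested in the call — 20 when the full published summary
table (4 demographic variables, IDEA total, 4 IDEA subscales, 11 EDI-2
subscales) is used. The summary-statistics route and the raw-data route are
algebraically identical and tested to agree to 1e-10.

## Problem sizes and seeds

All simulations are seeded (`numpy.random.default_rng`); identical
configuration implies byte-identical pipeline outputs, which the test suite
asserts at the shipped quickstart profile. Test and acceptance problem
sizes — e.g. recovery at n = 5000, coverage with 200 datasets x 200
replicates on a 3-node model, stability nulls with 25 seeds x 40 replicates
— are chosen so each statistical property is measured with useful
Monte-Carlo resolution while the whole suite stays desk-scale; the numbered
analysis drivers use n = 84 (study scale) plus an n = 2000 validation
sample for the same reason.

## Known limitations

- Pearson correlations on subscale totals; no polychoric/nonparanormal
  option.
- The sparse stand-in truth understates real-data connectivity (see above);
  absolute centrality values and CS magnitudes at n = 84 are not comparable
  to analyses of real samples.
- Percentile edge CIs inherit lasso shrinkage bias (documented above).
- No bootstrapped difference tests between edges or centralities; no bridge
  or expected-influence centralities; undirected Gaussian models only.
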