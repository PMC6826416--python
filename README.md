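# ednet

Regularized partial-correlation network analysis for eating-disorder
questionnaire data: EBIC-glasso estimation, weighted centrality indices,
bootstrap accuracy and stability diagnostics, and Bonferroni-corrected group
comparisons — together with a synthetic-data generator that emulates a
reference clinical sample of 84 anorexia nervosa patients (57 restricting,
27 binge-purging) assessed with the four IDEA embodiment subscales
(GEO, OM, EB, S) and the eleven EDI-2 subscales (IN, MF, SI, BD, P, ID, I,
DT, BU, IA, ASC).

The package is aimed at researchers who want a fully scripted, testable
version of the standard psychometric network workflow: because raw clinical
data of this kind are rarely shared, every stage here can be exercised and
validated against a known ground-truth model built from published summary
statistics (subscale means/SDs and the strongest reported edges).

## The model

Subscale scores `x ~ N(mu, Sigma)` are modelled as a Gaussian graphical
model: the precision matrix `K = Sigma^-1` encodes conditional independence,
and the network's edge weights are the partial correlations

    w_ij = -K_ij / sqrt(K_ii * K_jj).

`K` is estimated by the graphical lasso,

    max_K  log det K - tr(S K) - lambda * sum_{i != j} |K_ij|,

over a descending 100-point penalty path from `lambda_max = max|S_ij|`, and
the penalty is selected by the Extended Bayesian Information Criterion

    EBIC = -n [log det K - tr(S K)] + E log n + 4 E gamma log p,

with `E` the number of nonzero edges and `gamma = 0.5` (conservative
selection that suppresses spurious edges).

On the selected network the package computes per-node **strength**
(`sum_j |w_ij|`), **closeness** (inverse total shortest-path distance with
edge length `1/|w|`) and **betweenness** (shortest paths through the node),
plus their z-scores; edge-weight **95% bootstrap CIs** (nonparametric,
subjects resampled with replacement, default 2500 replicates); the
**correlation-stability (CS) coefficient** from the case-dropping bootstrap
(largest share of cases droppable while ≥95% of replicates still correlate
≥0.7 with the full-sample centralities; ≥0.25 is considered adequate); and
per-variable **Welch t-tests with Bonferroni correction** between the two
diagnostic subtypes, from raw data or from published summary statistics.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_estimate_network.py
```

prints (abridged):

```
[n84] n=84: lambda=0.3647, EBIC=1260.0, 0 edges (0/8 ground-truth edges kept)
[large] n=2000: lambda=0.0583, EBIC=28313.4, 11 edges (8/8 ground-truth edges kept)
node_i node_j  weight
    IN     SI   0.393
    OM      S   0.342
    OM     DT   0.246
    ...
```

The two lines summarize the estimator's behaviour under these study
conditions: at the study scale (n = 84) the gamma = 0.5 EBIC keeps no edges
of this deliberately sparse 8-edge ground truth (real questionnaire data
carry much more shared variance than the stand-in model), while at n = 2000
all 8 true edges are recovered — `IN–SI` (truth 0.44) and `OM–S` (truth
0.42) strongest, slightly shrunk by the lasso — plus three near-zero
spurious edges. `analysis/03_centrality.py` then ranks nodes by strength
(IA, OM, S and EB top the ground-truth network), `analysis/04_stability.py`
reports edge CIs and CS coefficients (strength CS = 0.75 on the validation
sample, 0 at n = 84), and `analysis/05_group_comparison.py` reproduces the
subtype contrast: bulimia (BU) is the only variable of 20 surviving
Bonferroni correction (Welch t = -4.68, adjusted p = 0.0012).

The same stages are available as a CLI (`ednet simulate | estimate |
centrality | stability | compare | run`) and as one orchestrated run:

```sh
ednet run --config configs/quickstart.yaml   # ~1 min; faithful.yaml = 2500 boots
```

## Layout

- `src/ednet/` — the library: `datasets` (ground-truth models, simulation),
  `estimation` (correlations, glasso, EBIC selection), `centrality`,
  `stability` (edge bootstrap, case-dropping, CS), `comparison`
  (t-tests, Bonferroni), `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `configs/` — quickstart and analysis-grade pipeline profiles.
- `docs/methods.md` — modelling assumptions, numerical choices, limitations.
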