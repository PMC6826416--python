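# Quickstart profile: full pipeline on a synthetic reference sample in ~1 min.
# Bootstrap replicates are reduced (500 edge / 50 case) for desk runtime;
# see faithful.yaml for the analysis-grade settings.
output_dir: results/quickstart
synthetic: {n: 84, seed: 0}
gamma: 0.5
n_lambda: 100
lambda_min_ratio: 0.01
n_boots_edges: 500
n_boots_cases: 50
drop_proportions: [0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75]
stability_seed: 0
cs_threshold: 0.7
cs_quantile: 0.95
comparison_variant: welch
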