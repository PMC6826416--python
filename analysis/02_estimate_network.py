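#!/usr/bin/env python
"""Estimate the regularized partial-correlation networks.

Runs the graphical lasso over a 100-point penalty path with EBIC (gamma =
0.5) selection, at the study scale (n = 84) and on the large validation
sample.  With only the 8 strongest published edges in the generator and
nothing else, the conservative EBIC keeps few or no edges at n = 84 — real
questionnaire data carry far more shared variance than this sparse stand-in
— while at n = 2000 every true edge is recovered.
"""

import json
from pathlib import Path

import pandas as pd

from ednet.datasets import REFERENCE_EDGES
from ednet.estimation import GlassoConfig, select_network
from ednet.io import read_subscale_csv

OUT = Path("results")
cfg = GlassoConfig(gamma=0.5)
true_pairs = {frozenset((a, b)) for a, b, _ in REFERENCE_EDGES}

for tag, path in (("n84", "sample.csv"), ("large", "sample_large.csv")):
    data = read_subscale_csv(OUT / path)
    net = select_network(data, cfg)
    edges = pd.DataFrame(net.edge_list(), columns=["node_i", "node_j", "weight"])
    edges.to_csv(OUT / f"edge_list_{tag}.csv", index=False)
    pd.DataFrame(net.weights, index=net.node_labels, columns=net.node_labels).to_csv(
        OUT / f"weight_matrix_{tag}.csv"
    )
    (OUT / f"network_summary_{tag}.json").write_text(
        json.dumps({"lambda": net.lambda_selected, "ebic": net.ebic_selected,
                    "n_edges": net.n_edges}, indent=1)
    )
    kept_true = sum(1 for a, b, _ in net.edge_list() if frozenset((a, b)) in true_pairs)
    print(f"[{tag}] n={data.n}: lambda={net.lambda_selected:.4f}, "
          f"EBIC={net.ebic_selected:.1f}, {net.n_edges} edges "
          f"({kept_true}/{len(true_pairs)} ground-truth edges kept)")
    if net.n_edges:
        print(edges.sort_values("weight", key=abs, ascending=False)
              .round(3).to_string(index=False))
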