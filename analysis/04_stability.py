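#!/usr/bin/env python
"""Accuracy and stability of the estimated networks.

Nonparametric bootstrap (500 replicates here; configs/faithful.yaml uses
2500) gives 95% quantile CIs per edge weight; the case-dropping bootstrap
re-estimates the network on shrinking subsamples and yields the correlation
stability (CS) coefficient per centrality index — the largest share of cases
droppable while >= 95% of replicates still correlate >= 0.7 with the
full-sample centralities.  CS below 0.25 is conventionally inadequate.  Both
diagnostics are run at the study scale (n = 84) and on the validation sample.
"""

import json
import warnings
from pathlib import Path

from ednet.estimation import GlassoConfig
from ednet.io import read_subscale_csv
from ednet.stability import bootstrap_edges, case_drop_bootstrap

OUT = Path("results")
cfg = GlassoConfig(gamma=0.5)

summary = {}
for tag, path in (("n84", "sample.csv"), ("large", "sample_large.csv")):
    data = read_subscale_csv(OUT / path)
    boot = bootstrap_edges(data, cfg, n_boots=500, seed=0)
    tbl = boot.table()
    tbl.to_csv(OUT / f"edge_cis_{tag}.csv", index=False)
    nonzero = tbl[tbl.observed != 0]
    print(f"[{tag}] edge bootstrap ({boot.n_boots} replicates): "
          f"{len(nonzero)} nonzero observed edges")
    if len(nonzero):
        print(nonzero.round(3).to_string(index=False))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stab = case_drop_bootstrap(data, cfg, n_boots=50, seed=1)
    stab.table().to_csv(OUT / f"stability_correlations_{tag}.csv", index=False)
    cs = stab.cs()
    summary[tag] = cs
    print(f"[{tag}] CS coefficients (threshold 0.7, 95% of replicates): {cs}")

(OUT / "stability_summary.json").write_text(json.dumps({"cs": summary}, indent=1))
print("\nnote: with only 8 true edges in the generator, the n = 84 network is "
      "empty or near-empty, so its CS is 0 by construction; the validation "
      "sample shows the stability the method reaches when edges are estimable")
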