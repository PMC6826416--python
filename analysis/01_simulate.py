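#!/usr/bin/env python
"""Simulate the reference questionnaire samples.

Draws the study-scale sample of 84 subjects (57 restricting, 27
binge-purging) from the ground-truth sparse partial-correlation model with
the published subscale marginals, plus a large validation sample (n = 2000)
from the same model used downstream to show what the estimator recovers when
data are plentiful.
"""

from pathlib import Path

from ednet.datasets import reference_dataset, reference_model
from ednet.io import write_subscale_csv

OUT = Path("results")
OUT.mkdir(exist_ok=True)

model = reference_model()
model.to_json(OUT / "ground_truth_model.json", seed=0)

data = reference_dataset(n=84, seed=0)
write_subscale_csv(data, OUT / "sample.csv")
print(f"wrote results/sample.csv: n={data.n} subjects x p={data.p} subscales "
      f"({(data.group == 'restricting').sum()} restricting, "
      f"{(data.group == 'binge_purging').sum()} binge-purging)")

large = reference_dataset(n=2_000, seed=1)
write_subscale_csv(large, OUT / "sample_large.csv")
print(f"wrote results/sample_large.csv: n={large.n} validation sample")
print(f"ground-truth model: {len(model.node_labels)} nodes, "
      f"{(model.partials != 0).sum() // 2} edges (results/ground_truth_model.json)")
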