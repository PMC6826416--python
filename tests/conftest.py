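import numpy as np
import pytest

from ednet.estimation import PartialCorrelationNetwork


def make_network(p, edges, labels=None):
    """Build a PartialCorrelationNetwork directly from (i, j, w) index triples."""
    w = np.zeros((p, p))
    for i, j, val in edges:
        w[i, j] = w[j, i] = val
    return PartialCorrelationNetwork(
        weights=w,
        node_labels=labels or [f"N{k}" for k in range(p)],
        lambda_selected=0.0,
        ebic_selected=0.0,
    )


@pytest.fixture
def three_node_path():
    # A - B - C with |w| = 0.5 on both edges
    return make_network(3, [(0, 1, 0.5), (1, 2, 0.5)])


@pytest.fixture
def reference_truth_network():
    """The generator's ground-truth partial-correlation network as a network object."""
    from ednet.datasets import reference_model

    model = reference_model()
    return PartialCorrelationNetwork(
        weights=model.partials,
        node_labels=list(model.node_labels),
        lambda_selected=0.0,
        ebic_selected=0.0,
    )
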