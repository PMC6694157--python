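import numpy as np
import pytest

import pathextend as px
from pathextend.kwalks import transition_matrix


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic preset: 200 genes, 5 pathways of 15, 3 bridges."""
    spec = px.FixtureSpec(seed=11)
    expr, meth, pmap, labels, edges, collection, truth = px.generate_bundle(spec)
    return {
        "spec": spec, "expr": expr, "meth": meth, "pmap": pmap,
        "labels": labels, "edges": edges, "collection": collection, "truth": truth,
    }


@pytest.fixture(scope="session")
def default_networks(default_bundle):
    b = default_bundle
    nets = {}
    for phenotype in ("case", "control"):
        blocks = px.build_feature_blocks(
            b["expr"], b["meth"], b["pmap"], b["labels"].samples_of(phenotype)
        )
        nets[phenotype] = px.build_weighted_network(blocks, b["edges"], phenotype)
    return nets


@pytest.fixture(scope="session")
def default_tms(default_networks):
    return {ph: transition_matrix(net) for ph, net in default_networks.items()}


@pytest.fixture(scope="session")
def mini_bundle():
    spec = px.mini_spec(7)
    expr, meth, pmap, labels, edges, collection, truth = px.generate_bundle(spec)
    return {
        "spec": spec, "expr": expr, "meth": meth, "pmap": pmap,
        "labels": labels, "edges": edges, "collection": collection, "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
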