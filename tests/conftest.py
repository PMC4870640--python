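import itertools

import networkx as nx
import numpy as np
import pytest


def set_partitions(nodes):
    """All partitions of a node list (restricted-growth-string enumeration)."""
    n = len(nodes)
    a = [0] * n
    b = [1] * n
    while True:
        yield {nodes[i]: a[i] for i in range(n)}
        i = n - 1
        while i > 0 and a[i] == b[i - 1]:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i] + 1)
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[i]


def random_abundance_table(rng, n_species=8, n_samples=6, sparsity=0.5):
    """Small random column-normalized table with zeros."""
    import pandas as pd

    X = rng.random((n_species, n_samples))
    X[rng.random(X.shape) < sparsity] = 0.0
    X[0, X.sum(axis=0) == 0] = 1.0  # keep columns normalizable
    X /= X.sum(axis=0)
    return pd.DataFrame(X, index=[f"sp{i}" for i in range(n_species)],
                        columns=[f"s{j}" for j in range(n_samples)])


@pytest.fixture
def triangle_pendant():
    """Triangle A-B-C with pendant edge C-D."""
    return nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])


@pytest.fixture(scope="session")
def planted_cohort():
    """120-species / 120-sample 4-module cohort network + ground truth."""
    from coocnet import cooccurrence as co
    from coocnet.synthetic_data import four_module_spec, generate_cohort

    spec = four_module_spec(120, 120, seed=2)
    table, truth = generate_cohort(spec)
    net, removed = co.build_network(table)
    return {"spec": spec, "table": table, "truth": truth, "net": net,
            "removed": removed}


@pytest.fixture(scope="session")
def hub_core_cohort():
    """Planted rich-club cohort (promoted hub core) network."""
    from coocnet import cooccurrence as co
    from coocnet.synthetic_data import generate_cohort, hub_core_spec

    spec = hub_core_spec(120, 120, n_hubs=8, seed=2)
    table, truth = generate_cohort(spec)
    net, _ = co.build_network(table)
    return {"spec": spec, "table": table, "truth": truth, "net": net}
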