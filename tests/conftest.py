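import io

import numpy as np
import pytest

import digiprot as dp
from digiprot import phylo as ph


@pytest.fixture(scope="session")
def worked_proteome():
    """Ingested worked-example fixture: one Agaricus bisporus record."""
    text = dp.worked_example_fixture()
    return dp.ingest_genbank(io.StringIO(text))


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Two-profile synthetic dataset small enough for fast end-to-end runs."""
    out = tmp_path_factory.mktemp("dataset")
    profiles = [
        dp.GroupProfile("Metazoa", 595, 439, 10.1, n_species=2, genes_per_species=400),
        dp.GroupProfile("Streptophyta", 436, 363, 5.7, n_species=2, genes_per_species=400),
    ]
    manifest = dp.simulate_dataset(profiles, out, seed=11)
    return out, manifest


def random_bifurcating_tree(n_leaves: int, rng: np.random.Generator) -> ph.PhyloTree:
    """Random rooted bifurcating tree with uniform branch lengths."""
    nodes = [
        ph.Node(name=f"L{i}", length=float(rng.uniform(0.2, 2.0)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        parent = ph.Node(length=float(rng.uniform(0.2, 2.0)))
        parent.add(a)
        parent.add(b)
        nodes.append(parent)
    nodes[0].length = 0.0
    return ph.PhyloTree(root=nodes[0])
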