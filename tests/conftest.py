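import numpy as np
import pytest

from htipred.kg_data import (
    KnowledgeGraph,
    SyntheticSpec,
    generate_synthetic_hti,
    generate_synthetic_kg,
    split_dataset,
)


@pytest.fixture(scope="session")
def tiny_kg() -> KnowledgeGraph:
    """Three typed entities, two triples."""
    return KnowledgeGraph(
        entities=(("h1", "herb"), ("t1", "target"), ("s1", "symptom")),
        triples=(("h1", "herb-target", "t1"), ("h1", "herb-symptom", "s1")),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """The planted-block benchmark (40 herbs, 80 targets, 4 blocks) with split."""
    spec = SyntheticSpec(seed=7)
    base = generate_synthetic_hti(spec)
    ds = split_dataset(base.positives, seed=18, herbs=base.herbs, targets=base.targets)
    return ds, spec


@pytest.fixture(scope="session")
def planted_kg(planted_dataset):
    ds, spec = planted_dataset
    return generate_synthetic_kg(spec, ds)


@pytest.fixture(scope="session")
def two_clique_kg() -> KnowledgeGraph:
    """Two disjoint 8-cliques; the classic embedding-separation toy."""
    entities = tuple((f"n{i}", "herb") for i in range(16))
    triples = []
    for block in (range(8), range(8, 16)):
        block = list(block)
        for a in block:
            for b in block:
                if a < b:
                    triples.append((f"n{a}", "linked", f"n{b}"))
    return KnowledgeGraph(entities=entities, triples=tuple(triples))


def random_bipartite_dataset(n_herbs: int, n_targets: int, density: float, seed: int):
    """Uniformly random bipartite positives with an 8:1:1 split."""
    rng = np.random.default_rng(seed)
    herbs = tuple(f"herb:H{i:03d}" for i in range(n_herbs))
    targets = tuple(f"target:T{j:03d}" for j in range(n_targets))
    adj = rng.random((n_herbs, n_targets)) < density
    for i in range(n_herbs):  # keep every herb connected
        if not adj[i].any():
            adj[i, rng.integers(n_targets)] = True
    positives = {(herbs[i], targets[j]) for i, j in zip(*np.nonzero(adj))}
    return split_dataset(positives, seed=seed, herbs=herbs, targets=targets)
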