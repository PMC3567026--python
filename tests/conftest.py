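import numpy as np
import pytest

from rmtnet import (
    Network,
    build_similarity_matrix,
    extract_network,
    find_threshold,
    generate_modular_expression,
)

PLANTED = dict(
    n_genes=600, n_samples=100, n_modules=5, module_size=20, loading=0.92
)
#: scan floor for planted-module data: the Poisson-to-GOE transition of this
#: generator sits near r ~ 0.37 (100 samples), below the library default.
PLANTED_RMT = dict(t_min=0.2)
PLANTED_SEED = 1


def make_network(pairs) -> Network:
    edges = {}
    for e in pairs:
        if len(e) == 3:
            a, b, w = e
        else:
            (a, b), w = e, 1.0
        if b < a:
            a, b = b, a
        edges[(a, b)] = w
    return Network(edges)


@pytest.fixture(scope="session")
def planted_pipeline():
    """ccm -> rmm -> extract on planted-module data (shared, heavy)."""
    em, truth = generate_modular_expression(**PLANTED, seed=PLANTED_SEED)
    sm = build_similarity_matrix(em)
    result = find_threshold(sm, **PLANTED_RMT)
    net = extract_network(sm, result.final_threshold)
    return em, truth, sm, result, net


@pytest.fixture()
def triangle():
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture()
def two_triangles():
    """Two triangles joined at the single shared node c."""
    return make_network(
        [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("c", "e"), ("d", "e")]
    )


@pytest.fixture()
def clique4_pendant():
    nodes = ["a", "b", "c", "d"]
    pairs = [(x, y) for i, x in enumerate(nodes) for y in nodes[i + 1 :]]
    pairs.append(("d", "e"))
    return make_network(pairs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
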