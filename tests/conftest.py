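import pytest

import stmrf


@pytest.fixture(scope="session")
def default_graph():
    """Four disconnected lattice countries, 37 districts."""
    return stmrf.generate_graph()


@pytest.fixture(scope="session")
def toy_graph():
    """Path of four areas plus one isolate (two components)."""
    ids = ["a", "b", "c", "d", "e"]
    return stmrf.build_adjacency([("a", "b"), ("b", "c"), ("c", "d")], ids)


@pytest.fixture(scope="session")
def toy_panel(toy_graph):
    panel, truth = stmrf.generate_panel(
        toy_graph, T=3, k=1, beta=[0.4],
        hyper={"sigma2_u": 0.05, "delta2_v": 0.1, "sigma2_gamma": 0.1,
               "sigma2_phi": 0.02, "sigma2_psi": 0.0},
        interaction=None, seed=7, n_range=(800, 3000))
    return panel, truth


def random_disconnected_graph(rng, max_components=5):
    """Erdos-Renyi components glued into one disconnected graph."""
    C = int(rng.integers(1, max_components + 1))
    ids, edges, offset = [], [], 0
    for c in range(C):
        n = int(rng.integers(2, 8))
        comp_ids = [f"g{c}n{i}" for i in range(n)]
        # random spanning tree keeps the component connected
        for i in range(1, n):
            j = int(rng.integers(0, i))
            edges.append((comp_ids[i], comp_ids[j]))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    edges.append((comp_ids[i], comp_ids[j]))
        ids += comp_ids
        offset += n
    return stmrf.build_adjacency(edges, ids)
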