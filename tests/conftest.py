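import numpy as np
import pytest

from pathflux.network import PathwayNetwork


def make_path_network(n: int, weight: float = 10.0, exits=()) -> PathwayNetwork:
    """Directed path V1 -> V2 -> ... -> Vn with uniform edge weight."""
    ids = [f"V{i + 1}" for i in range(n)]
    edges = [(a, b, weight) for a, b in zip(ids, ids[1:])]
    return PathwayNetwork.from_records(ids, edges, exit_nodes=exits)


def random_digraph(rng: np.random.Generator, max_nodes: int = 12) -> PathwayNetwork:
    """Random weighted digraph with at least one sink (usable as exit)."""
    n = int(rng.integers(2, max_nodes + 1))
    ids = [f"V{i + 1}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            # node Vn kept as a sink so detect_exits always succeeds
            if i != j and i != n - 1 and rng.random() < 0.3:
                w = float(rng.uniform(10.0, 100.0))
                edges.append((ids[i], ids[j], w))
    return PathwayNetwork.from_records(ids, edges)


def brute_force_distances(net: PathwayNetwork) -> dict:
    """Floyd–Warshall all-pairs oracle, independent of the Dijkstra path."""
    ids = list(net.graph.nodes)
    idx = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (u, v), w in net.weights().items():
        d[idx[u], idx[v]] = min(d[idx[u], idx[v]], w)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return {
        (ids[i], ids[j]): d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    }


@pytest.fixture
def path3() -> PathwayNetwork:
    return make_path_network(3)


@pytest.fixture
def table2():
    from pathflux.synthetic import load_fixture

    return load_fixture("compounds_table2")


@pytest.fixture
def activity():
    from pathflux.synthetic import activity_fixture

    return activity_fixture()
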