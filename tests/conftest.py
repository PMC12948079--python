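import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def named_small_graphs():
    """Paths, cycles, stars, complete and complete-bipartite graphs <= 12 nodes."""
    graphs = []
    for n in range(2, 9):
        graphs.append((f"P{n}", nx.path_graph(n)))
    for n in range(3, 11):
        graphs.append((f"C{n}", nx.cycle_graph(n)))
    for leaves in range(2, 10):
        graphs.append((f"K1_{leaves}", nx.star_graph(leaves)))
    for n in range(2, 7):
        graphs.append((f"K{n}", nx.complete_graph(n)))
    for a, b in [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4), (5, 6), (2, 9)]:
        graphs.append((f"K{a}_{b}", nx.complete_bipartite_graph(a, b)))
    two_comp = nx.disjoint_union(nx.path_graph(4), nx.cycle_graph(5))
    graphs.append(("P4+C5", two_comp))
    return graphs


def random_small_graphs(count: int, max_n: int = 12, base_seed: int = 20_000):
    """Seeded Erdos–Renyi suite; density varies, disconnection is common."""
    import numpy as np

    rng = np.random.default_rng(base_seed)
    graphs = []
    for i in range(count):
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.05, 0.7))
        graphs.append((f"G{i}", nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))))
    return graphs


@pytest.fixture
def tiny_association_file(tmp_path):
    """Factory writing a small association TSV and returning its path."""

    def _write(rows, header=("plant", "metabolite"), sep="\t", name="assoc.tsv"):
        path = tmp_path / name
        lines = [sep.join(header)]
        lines += [sep.join(str(x) for x in row) for row in rows]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write


@pytest.fixture
def small_truth():
    """Small deterministic synthetic dataset with planted hubs."""
    from phytorank import SynthConfig, generate_annotations, generate_network

    cfg = SynthConfig(
        n_plants=120, n_metabolites=40, target_edges=320,
        max_metabolite_degree=30, n_planted_hubs=3, hub_metabolite_count=12,
        seed=424242,
    )
    truth = generate_network(cfg)
    generate_annotations(truth, known_fraction=0.8, seed=424243)
    return truth
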