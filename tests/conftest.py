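import numpy as np
import pandas as pd
import pytest

from micronet import AbundanceTable, make_basis_network, simulate_counts


@pytest.fixture(scope="session")
def planted_gt():
    """Default-density planted basis network (30 taxa, 3 modules)."""
    return make_basis_network(30, 3, p_within=0.1, p_between=0.01,
                              neg_frac=0.3, corr_strength=0.8, seed=11)


@pytest.fixture(scope="session")
def planted_table(planted_gt):
    """300 samples simulated under the planted basis."""
    return simulate_counts(planted_gt, 300, depth=20000, seed=11)


@pytest.fixture()
def small_table():
    """Hand-built 6-sample x 5-taxon table with two groups and 2 controls."""
    counts = pd.DataFrame(
        [
            [10, 0, 5, 1, 0],
            [8, 2, 7, 0, 0],
            [12, 1, 6, 2, 0],
            [9, 0, 4, 1, 0],
            [0, 0, 0, 0, 50],
            [0, 1, 0, 0, 40],
        ],
        index=[f"s{i}" for i in range(6)],
        columns=["tA", "tB", "tC", "tD", "tE"],
    )
    meta = pd.DataFrame(
        {
            "group": ["g1", "g1", "g2", "g2", "blank", "blank"],
            "timepoint": ["t1"] * 4 + ["none"] * 2,
            "is_control": [False] * 4 + [True] * 2,
        },
        index=counts.index,
    )
    return AbundanceTable(counts, meta)


def brute_force_reachable_pairs(adj: dict, nodes: set) -> int:
    """Oracle: count ordered mutually-reachable pairs by per-node BFS."""
    total = 0
    for start in nodes:
        seen = {start}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):  # noqa: B905
                    if v in nodes and v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        total += len(seen) - 1
    return total
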