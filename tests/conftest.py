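"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from graphscan import CountTable, CountyGraph


def make_table(
    counties,
    events,
    baselines,
    year=2015,
    events_b=None,
    baselines_b=None,
):
    """CountTable with the claims layer set explicitly.

    The beneficiary layer defaults to a copy of the claims layer.
    """
    events = list(events)
    baselines = list(baselines)
    events_b = events if events_b is None else list(events_b)
    baselines_b = baselines if baselines_b is None else list(baselines_b)
    return CountTable(
        pd.DataFrame(
            {
                "county": list(counties),
                "year": year,
                "total_beneficiaries": baselines_b,
                "opioid_beneficiaries": events_b,
                "total_claims": baselines,
                "opioid_claims": events,
            }
        )
    )


def path_graph(n, prefix="n"):
    g = nx.path_graph(n)
    g = nx.relabel_nodes(g, {i: f"{prefix}{i:02d}" for i in range(n)})
    return CountyGraph(g)


def random_connected_graph(n, p, seed):
    """Random connected graph with sorted string node labels."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    return CountyGraph(nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes}))


def random_count_table(graph, rng, rate=0.1, base_lo=50, base_hi=500, year=2015):
    nodes = graph.nodes
    base = rng.integers(base_lo, base_hi, size=len(nodes))
    ev = np.minimum(rng.poisson(rate * base), base)
    return make_table(nodes, ev, base, year=year)


def unit_square(x0, y0):
    return {
        "type": "Polygon",
        "coordinates": [
            [[x0, y0], [x0 + 1, y0], [x0 + 1, y0 + 1], [x0, y0 + 1], [x0, y0]]
        ],
    }


def square_grid_geojson(rows, cols):
    features = []
    for r in range(rows):
        for c in range(cols):
            features.append(
                {
                    "type": "Feature",
                    "properties": {"county": f"g{r}{c}"},
                    "geometry": unit_square(c, r),
                }
            )
    return {"type": "FeatureCollection", "features": features}


@pytest.fixture(scope="session")
def grid36():
    from graphscan import make_grid_graph

    return make_grid_graph(6, 6)
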