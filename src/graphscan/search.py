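"""Connected-cluster search: exact oracle, scalable heuristic, ranked
secondary clusters, and a circular-window baseline.

The search space is the family of county sets that induce a connected
subgraph of the contiguity graph, up to a configured maximum size.  On
small graphs every such set can be enumerated and the optimum found
exactly; at state scale the heuristic (multi-seed greedy growth with
best-prefix tracking plus a 1-swap local search per seed) is used, and its
adequacy is enforced by agreement with the exact oracle on graphs where
both run.

The circular-window baseline mimics the classic distance-based scan:
candidate zones are a county plus its k nearest counties by great-circle
centroid distance, grown until the zone holds a configured fraction of the
total baseline.  Zones need not be graph-connected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from ._core import EXPECTATION, KULLDORFF, score_cb, search_core
from .counts import ClusterCounts, CountTable
from .graph import CountyGraph
from .statistics import (
    CONTINUITY_CONSTANT,
    ScoreValue,
    expectation_poisson_score,
    kulldorff_poisson_score,
)

STATISTICS = ("kulldorff_poisson", "expectation_poisson")
EXACT_NODE_BUDGET = 16


class BudgetExceededError(ValueError):
    """Exact enumeration refused: graph too large; use search_best_cluster."""


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the cluster search.

    ``max_size`` bounds the cluster cardinality (default 30, the size of
    the largest cluster the method is expected to report at state scale).
    ``history_years`` is required for the expectation-based statistic and
    ignored otherwise.
    """

    statistic: str = "kulldorff_poisson"
    count_kind: str = "claims"
    max_size: int = 30
    n_secondary: int = 1
    seed: int = 0
    history_years: tuple[int, ...] = ()
    continuity: float = CONTINUITY_CONSTANT

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        if self.n_secondary < 0:
            raise ValueError("n_secondary must be >= 0")
        if self.statistic == "expectation_poisson" and not self.history_years:
            raise ValueError("expectation_poisson requires history_years")


@dataclass(frozen=True)
class Cluster:
    """A connected county set with its score and (optionally) significance."""

    members: tuple[str, ...]
    score: ScoreValue
    statistic: str
    count_kind: str
    year: int
    rank: int = 1
    p_value: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class ScanData:
    """Per-county arrays the search core consumes, in sorted node order.

    For the Kulldorff statistic ``baselines`` holds the exposure counts and
    the roster totals are used; for the expectation-based statistic
    ``baselines`` holds the per-county expected counts built from history
    and the totals are unused.
    """

    graph: CountyGraph
    nodes: tuple[str, ...]
    events: np.ndarray
    baselines: np.ndarray
    total_event: float
    total_baseline: float
    kind: int
    statistic: str
    count_kind: str
    year: int

    def score_members(self, member_ids: Sequence[str]) -> ScoreValue:
        idx = {c: i for i, c in enumerate(self.nodes)}
        sel = [idx[c] for c in member_ids]
        c = float(self.events[sel].sum())
        b = float(self.baselines[sel].sum())
        if self.kind == KULLDORFF:
            return kulldorff_poisson_score(
                ClusterCounts(
                    event=int(round(c)),
                    baseline=int(round(b)),
                    total_event=int(round(self.total_event)),
                    total_baseline=int(round(self.total_baseline)),
                )
            )
        return expectation_poisson_score(c, b)


def build_scan_data(
    graph: CountyGraph, table: CountTable, year: int, config: SearchConfig
) -> ScanData:
    nodes = tuple(graph.nodes)
    if config.statistic == "kulldorff_poisson":
        ev, base = table.arrays(nodes, year, config.count_kind)
        ev = ev.astype(np.float64)
        base = base.astype(np.float64)
        return ScanData(
            graph, nodes, ev, base, float(ev.sum()), float(base.sum()),
            KULLDORFF, config.statistic, config.count_kind, year,
        )
    ev, _ = table.arrays(nodes, year, config.count_kind)
    history = np.zeros(len(nodes), dtype=np.float64)
    for y in config.history_years:
        hev, _ = table.arrays(nodes, int(y), config.count_kind)
        history += hev
    expected = history / len(config.history_years)
    expected = np.maximum(expected, config.continuity)
    return ScanData(
        graph, nodes, ev.astype(np.float64), expected, 0.0, 0.0,
        EXPECTATION, config.statistic, config.count_kind, year,
    )


# ---------------------------------------------------------------------------
# exact enumeration oracle

def enumerate_connected_subsets(
    graph: CountyGraph, max_size: int
) -> Iterator[frozenset[str]]:
    """Yield every connected node subset of size 1..max_size exactly once.

    Enumeration is rooted at each subset's minimum node (in sorted-id
    order) and extends through exclusive neighbourhoods, so no subset is
    produced twice.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    nodes = graph.nodes
    idx = {c: i for i, c in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for u, v in graph.graph.edges:
        adj[idx[u]].append(idx[v])
        adj[idx[v]].append(idx[u])
    for row in adj:
        row.sort()

    def extend(root: int, members: list[int], ext: list[int], seen: set[int]):
        yield frozenset(nodes[i] for i in members)
        if len(members) == max_size:
            return
        while ext:
            w = ext.pop()
            new_seen = seen | {w}
            fresh = [u for u in adj[w] if u > root and u not in new_seen]
            new_seen.update(fresh)
            yield from extend(root, members + [w], ext + sorted(fresh), new_seen)

    for root in range(len(nodes)):
        seen = {root} | {u for u in adj[root] if u > root}
        ext = sorted(u for u in adj[root] if u > root)
        yield from extend(root, [root], ext, seen)


def exact_best_cluster(
    graph: CountyGraph,
    table: CountTable,
    year: int,
    config: SearchConfig,
    node_budget: int = EXACT_NODE_BUDGET,
) -> Cluster:
    """Argmax of the statistic over all connected subsets, by enumeration.

    Refuses graphs above ``node_budget`` nodes; the heuristic
    :func:`search_best_cluster` covers those.
    """
    if graph.n_nodes > node_budget:
        raise BudgetExceededError(
            f"{graph.n_nodes} nodes exceeds the exact-enumeration budget "
            f"({node_budget}); use search_best_cluster"
        )
    data = build_scan_data(graph, table, year, config)
    idx = {c: i for i, c in enumerate(data.nodes)}
    best_score = -1.0
    best_members: tuple[str, ...] = ()
    for subset in enumerate_connected_subsets(graph, config.max_size):
        members = tuple(sorted(subset))
        sel = [idx[c] for c in members]
        c = float(data.events[sel].sum())
        b = float(data.baselines[sel].sum())
        s = float(score_cb(c, b, data.total_event, data.total_baseline, data.kind))
        if s > best_score or (s == best_score and members < best_members):
            best_score = s
            best_members = members
    return Cluster(
        members=best_members,
        score=data.score_members(best_members),
        statistic=config.statistic,
        count_kind=config.count_kind,
        year=year,
    )


# ---------------------------------------------------------------------------
# heuristic search

def _core_search(data: ScanData, config: SearchConfig, active: np.ndarray):
    indptr, indices = data.graph.csr()
    score, member_idx = search_core(
        indptr, indices, data.events, data.baselines,
        data.total_event, data.total_baseline, data.kind,
        min(config.max_size, max(1, len(data.nodes))),
        active,
    )
    return float(score), [data.nodes[i] for i in member_idx]


def search_best_cluster(
    graph: CountyGraph, table: CountTable, year: int, config: SearchConfig
) -> Cluster:
    """Best connected cluster by the greedy + 1-swap heuristic."""
    data = build_scan_data(graph, table, year, config)
    active = np.ones(len(data.nodes), dtype=np.uint8)
    _, members = _core_search(data, config, active)
    members = tuple(sorted(members))
    return Cluster(
        members=members,
        score=data.score_members(members),
        statistic=config.statistic,
        count_kind=config.count_kind,
        year=year,
    )


def top_k_clusters(
    graph: CountyGraph, table: CountTable, year: int, config: SearchConfig
) -> list[Cluster]:
    """Ranked disjoint clusters: best cluster, remove its counties, repeat.

    Stops after 1 + n_secondary clusters or as soon as the best remaining
    score is 0 (a 0-score rank-1 cluster is still reported so the run has
    an explicit "nothing elevated" record).
    """
    data = build_scan_data(graph, table, year, config)
    active = np.ones(len(data.nodes), dtype=np.uint8)
    idx = {c: i for i, c in enumerate(data.nodes)}
    out: list[Cluster] = []
    for rank in range(1, config.n_secondary + 2):
        if not active.any():
            break
        score, members = _core_search(data, config, active)
        if score <= 0.0 and rank > 1:
            break
        members = tuple(sorted(members))
        out.append(
            Cluster(
                members=members,
                score=data.score_members(members),
                statistic=config.statistic,
                count_kind=config.count_kind,
                year=year,
                rank=rank,
            )
        )
        if score <= 0.0:
            break
        for c in members:
            active[idx[c]] = 0
    return out


# ---------------------------------------------------------------------------
# circular-window baseline

def _haversine_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) from (lon, lat) degrees."""
    lon = np.radians(coords[:, 0])[:, None]
    lat = np.radians(coords[:, 1])[:, None]
    dlon = lon - lon.T
    dlat = lat - lat.T
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2.0) ** 2
    return 2.0 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def circular_scan(
    graph: CountyGraph,
    table: CountTable,
    year: int,
    config: SearchConfig,
    max_baseline_fraction: float = 0.5,
) -> list[Cluster]:
    """Distance-based baseline scan over circular zones.

    For every county as centre, zones are the centre plus its k nearest
    counties (k = 0, 1, ...) while the zone baseline stays within
    ``max_baseline_fraction`` of the roster total.  Secondary zones follow
    the same disjoint-removal rule as the network search.
    """
    data = build_scan_data(graph, table, year, config)
    coords = graph.centroid_array()
    dist = _haversine_matrix(coords)
    n = len(data.nodes)
    if data.kind == KULLDORFF:
        frac_cap = max_baseline_fraction * data.total_baseline
    else:
        frac_cap = max_baseline_fraction * float(data.baselines.sum())
    active = np.ones(n, dtype=bool)
    out: list[Cluster] = []
    for rank in range(1, config.n_secondary + 2):
        if not active.any():
            break
        best_score = -1.0
        best_members: tuple[int, ...] = ()
        for center in range(n):
            if not active[center]:
                continue
            others = [j for j in np.argsort(dist[center], kind="stable") if active[j]]
            c = 0.0
            b = 0.0
            zone: list[int] = []
            for j in others:  # first element is the centre itself (distance 0)
                if b + data.baselines[j] > frac_cap or len(zone) >= config.max_size:
                    break
                zone.append(int(j))
                c += data.events[j]
                b += data.baselines[j]
                s = float(score_cb(c, b, data.total_event, data.total_baseline, data.kind))
                members = tuple(sorted(zone))
                if s > best_score or (s == best_score and members < best_members):
                    best_score = s
                    best_members = members
        if best_members == () or (best_score <= 0.0 and rank > 1):
            break
        ids = tuple(sorted(data.nodes[i] for i in best_members))
        out.append(
            Cluster(
                members=ids,
                score=data.score_members(ids),
                statistic=config.statistic,
                count_kind=config.count_kind,
                year=year,
                rank=rank,
            )
        )
        if best_score <= 0.0:
            break
        for i in best_members:
            active[i] = False
    return out
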