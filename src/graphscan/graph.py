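"""County contiguity graphs.

Counties are identified by opaque strings (FIPS codes in real data;
grid labels in simulations).  Two counties are adjacent when they share a
boundary, and the scan statistic is maximised over county sets that induce
a connected subgraph of this contiguity graph.  Graphs may be disconnected
(islands, independent cities separated by water).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import shape


class GraphValidationError(ValueError):
    """Raised when an adjacency source violates the contiguity-graph contract."""


@dataclass
class CountyGraph:
    """Undirected simple graph over county identifiers.

    Parameters
    ----------
    graph
        ``networkx.Graph`` whose nodes are county-id strings.  Self loops
        are rejected; ``networkx`` already collapses duplicate edges.
    centroids
        Optional map county id -> (longitude, latitude) in degrees,
        required only by the circular-window baseline scan.

    The node order used everywhere downstream (CSR arrays, tie-breaking)
    is the sorted county-id order, so results do not depend on insertion
    order.  Treat instances as immutable after construction.
    """

    graph: nx.Graph
    centroids: dict[str, tuple[float, float]] | None = None
    _csr_cache: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        loops = list(nx.nodes_with_selfloops(self.graph))
        if loops:
            raise GraphValidationError(f"self-loop on county {loops[0]!r}")
        if self.centroids is not None:
            missing = set(self.centroids) - set(self.graph.nodes)
            if missing:
                raise GraphValidationError(
                    f"centroids for unknown counties: {sorted(missing)}"
                )

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.nodes)}

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def is_connected_subset(self, members: Iterable[str]) -> bool:
        members = set(members)
        if not members:
            return False
        sub = self.graph.subgraph(members)
        return nx.is_connected(sub)

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency in CSR form over the sorted node order."""
        if self._csr_cache is None:
            idx = self.node_index()
            indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            rows: list[list[int]] = []
            for i, u in enumerate(self.nodes):
                nbrs = sorted(idx[v] for v in self.graph.neighbors(u))
                rows.append(nbrs)
                indptr[i + 1] = indptr[i] + len(nbrs)
            indices = np.fromiter(
                (j for row in rows for j in row), dtype=np.int64, count=int(indptr[-1])
            )
            object.__setattr__(self, "_csr_cache", (indptr, indices))
        return self._csr_cache

    def centroid_array(self) -> np.ndarray:
        """(n, 2) array of (lon, lat) in sorted node order."""
        if self.centroids is None:
            raise GraphValidationError("graph carries no centroids")
        missing = [c for c in self.nodes if c not in self.centroids]
        if missing:
            raise GraphValidationError(f"missing centroid for counties {missing}")
        return np.array([self.centroids[c] for c in self.nodes], dtype=float)


def load_adjacency(
    source: str | Path | Iterable[tuple[str, str]],
    roster: Iterable[str] | None = None,
) -> CountyGraph:
    """Build a contiguity graph from an edge list.

    ``source`` is either a CSV path (header ``county_a,county_b``) or an
    iterable of id pairs.  The symmetric closure is applied, duplicate
    edges collapse, self-loops are rejected.  With a ``roster``, counties
    without any edge become isolated nodes and edges naming counties
    outside the roster are an error.
    """
    pairs: list[tuple[str, str]]
    if isinstance(source, (str, Path)):
        pairs = []
        with open(source, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header[:2]] != ["county_a", "county_b"]:
                raise GraphValidationError(
                    f"{source}: expected header 'county_a,county_b', got {header}"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not f.strip() for f in row):
                    continue
                if len(row) < 2 or not row[0].strip() or not row[1].strip():
                    raise GraphValidationError(f"{source}:{lineno}: malformed edge row {row}")
                pairs.append((row[0].strip(), row[1].strip()))
    else:
        pairs = [(str(a), str(b)) for a, b in source]

    g = nx.Graph()
    if roster is not None:
        roster_set = {str(c) for c in roster}
        g.add_nodes_from(roster_set)
    else:
        roster_set = None
    for a, b in pairs:
        if a == b:
            raise GraphValidationError(f"self-loop edge ({a!r},{b!r})")
        if roster_set is not None and (a not in roster_set or b not in roster_set):
            unknown = [c for c in (a, b) if c not in roster_set]
            raise GraphValidationError(f"edge ({a!r},{b!r}) references unknown counties {unknown}")
        g.add_edge(a, b)
    return CountyGraph(g)


def graph_from_boundaries(
    source: str | Path | dict, contiguity: str = "rook"
) -> CountyGraph:
    """Contiguity graph from county polygons in a GeoJSON FeatureCollection.

    Each feature carries the county id in property ``county``.  Under the
    ``rook`` rule two counties are adjacent when their boundaries share a
    segment of positive length; ``queen`` additionally accepts single-point
    (corner) contact.  Centroids are populated from the polygon centroids.
    """
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"contiguity must be 'rook' or 'queen', got {contiguity!r}")
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    else:
        doc = source
    geoms: dict[str, object] = {}
    for feat in doc.get("features", []):
        county = feat.get("properties", {}).get("county")
        if county is None:
            raise GraphValidationError("feature missing 'county' property")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise GraphValidationError(f"invalid geometry for county {county!r}")
        geoms[str(county)] = geom

    g = nx.Graph()
    g.add_nodes_from(geoms)
    names = sorted(geoms)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = geoms[a].intersection(geoms[b])
            if inter.is_empty:
                continue
            # overlapping layers (positive area) count as contiguity too
            shares_segment = inter.length > 0 or getattr(inter, "area", 0.0) > 0
            if shares_segment or contiguity == "queen":
                g.add_edge(a, b)
    centroids = {c: (geoms[c].centroid.x, geoms[c].centroid.y) for c in names}
    return CountyGraph(g, centroids=centroids)
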