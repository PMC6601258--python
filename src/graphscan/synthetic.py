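"""Synthetic county/provider data with the structure the analysis assumes.

The generator emulates county-level prescription surveillance data: a
contiguity graph (rook lattice), per-county baseline counts with a
right-skewed (log-normal) size distribution, Poisson event counts whose
rate is elevated inside one connected cluster, optional year-localised
rate changes, demographic covariates whose means differ inside/outside
the cluster, and a provider layer obtained by splitting county totals
across providers with specialty labels.

Under H0 (``cluster_rate == background_rate`` and no temporal change) the
data carry no spatial structure, which is what the type-I-error
experiments rely on.  Everything is driven by one scenario seed; the same
seed reproduces bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .characterize import COVARIATE_COLUMNS, PROVIDER_COLUMNS
from .counts import CountTable
from .graph import CountyGraph

logger = logging.getLogger(__name__)

#: covariate -> (outside mean, inside mean, sd); percentages on 0-100 scale.
#: Outside means approximate mid-Atlantic county demographics; by default
#: the cluster is demographically indistinguishable (no effect).
DEFAULT_COVARIATE_EFFECTS: dict[str, tuple[float, float, float]] = {
    "pct_african_american": (19.0, 19.0, 10.0),
    "pct_american_indian": (0.5, 0.5, 0.4),
    "pct_male": (49.0, 49.0, 1.5),
    "n_housing_units": (35000.0, 35000.0, 15000.0),
    "pct_medicaid": (15.0, 15.0, 5.0),
    "pct_medicare": (18.0, 18.0, 5.0),
    "pct_direct_purchase": (12.0, 12.0, 3.0),
    "pct_income_poverty_lt_0_5": (6.0, 6.0, 2.0),
}

DEFAULT_SPECIALTIES: tuple[tuple[str, float], ...] = (
    ("Family Practice", 0.28),
    ("Internal Medicine", 0.22),
    ("Nurse Practitioner", 0.15),
    ("Physician Assistant", 0.10),
    ("Dentist", 0.10),
    ("Physical Medicine and Rehabilitation", 0.05),
    ("Orthopedic Surgery", 0.05),
    ("Emergency Medicine", 0.05),
)


@dataclass(frozen=True)
class TemporalChange:
    """Multiply a region's event rate in one year only."""

    year: int
    multiplier: float
    members: tuple[str, ...] | None = None
    size: int = 6


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one simulated study.

    ``background_rate`` (mu) and ``cluster_rate`` (eta) are events per unit
    baseline; H1 scenarios set eta > mu, H0 scenarios set eta == mu.
    ``cluster_members=None`` selects a random connected set of
    ``cluster_size`` counties by random-walk growth.  ``baseline_mean`` and
    ``baseline_sigma`` parameterise the log-normal county-size layer
    (sigma is the dispersion of the underlying normal).
    """

    rows: int = 10
    cols: int = 10
    background_rate: float = 0.1
    cluster_rate: float = 0.2
    cluster_size: int = 6
    cluster_members: tuple[str, ...] | None = None
    baseline_mean: float = 5000.0
    baseline_sigma: float = 0.5
    years: tuple[int, ...] = (2015,)
    #: redraw baselines every year instead of holding county sizes fixed
    #: across years (fixed is the realistic default: county populations
    #: persist, so year-over-year event changes reflect rates, not sizes)
    baseline_redraw_each_year: bool = False
    temporal_change: TemporalChange | None = None
    covariate_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    n_providers_per_county: int = 5
    specialties: tuple[tuple[str, float], ...] = DEFAULT_SPECIALTIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.cluster_rate < self.background_rate:
            raise ValueError("cluster_rate must be >= background_rate")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be at least 1x1")

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        doc["covariate_effects"] = {k: list(v) for k, v in self.covariate_effects.items()}
        doc["specialties"] = [list(s) for s in self.specialties]
        return json.dumps(doc, indent=2, sort_keys=True)


@dataclass(frozen=True)
class SimulatedData:
    """Bundle of all generated tables plus the planted truth."""

    graph: CountyGraph
    counts: CountTable
    covariates: pd.DataFrame
    providers: pd.DataFrame
    cluster_members: tuple[str, ...]
    temporal_members: tuple[str, ...]
    scenario: SyntheticScenario


def make_grid_graph(rows: int, cols: int) -> CountyGraph:
    """Rook-adjacency lattice of rows x cols cells, centroids at cell centres."""
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    g = nx.Graph()
    centroids = {}
    for r in range(rows):
        for c in range(cols):
            node = _cell_id(r, c)
            g.add_node(node)
            centroids[node] = (float(c), float(r))
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                g.add_edge(_cell_id(r, c), _cell_id(r, c + 1))
            if r + 1 < rows:
                g.add_edge(_cell_id(r, c), _cell_id(r + 1, c))
    return CountyGraph(g, centroids=centroids)


def _cell_id(r: int, c: int) -> str:
    return f"c{r:02d}x{c:02d}"


def random_connected_subset(
    graph: CountyGraph, size: int, rng: np.random.Generator,
    exclude: Sequence[str] = (),
) -> tuple[str, ...]:
    """Random-walk growth of a connected county set of the requested size."""
    nodes = [n for n in graph.nodes if n not in set(exclude)]
    if size < 1 or size > len(nodes):
        raise ValueError(f"cannot grow a connected set of size {size}")
    excluded = set(exclude)
    for _attempt in range(200):
        seed_node = nodes[int(rng.integers(len(nodes)))]
        members = {seed_node}
        frontier = [v for v in graph.graph.neighbors(seed_node) if v not in excluded]
        while len(members) < size and frontier:
            nxt = frontier[int(rng.integers(len(frontier)))]
            members.add(nxt)
            frontier = sorted(
                {
                    v
                    for m in members
                    for v in graph.graph.neighbors(m)
                    if v not in members and v not in excluded
                }
            )
        if len(members) == size:
            return tuple(sorted(members))
    raise ValueError("could not grow a connected subset; graph too constrained")


def generate_counts(
    graph: CountyGraph,
    scenario: SyntheticScenario,
    cluster_members: Sequence[str],
    rng: np.random.Generator,
    temporal_members: Sequence[str] = (),
) -> CountTable:
    """Baselines log-normal, events Poisson at mu outside / eta inside.

    The beneficiary and claims layers are generated independently given
    the baselines.  A temporal change multiplies the affected region's
    event rate in its stated year only.  Events exceeding their baseline
    (possible when rates approach 1) are resampled, then capped.
    """
    nodes = graph.nodes
    cluster = set(cluster_members)
    unknown = cluster - set(nodes)
    if unknown:
        raise ValueError(f"cluster members not in graph: {sorted(unknown)[:5]}")
    temporal = set(temporal_members)
    tc = scenario.temporal_change
    mu_log = np.log(scenario.baseline_mean) - scenario.baseline_sigma**2 / 2.0
    layers = (
        ("total_beneficiaries", "opioid_beneficiaries"),
        ("total_claims", "opioid_claims"),
    )
    fixed_base: dict[tuple[str, str], int] = {}
    if not scenario.baseline_redraw_each_year:
        for node in nodes:
            for base_col, _ in layers:
                fixed_base[(node, base_col)] = max(
                    1, int(round(rng.lognormal(mu_log, scenario.baseline_sigma)))
                )

    records = []
    for year in scenario.years:
        for node in nodes:
            rate = (
                scenario.cluster_rate if node in cluster else scenario.background_rate
            )
            if tc is not None and year == tc.year and node in temporal:
                rate *= tc.multiplier
            row = {"county": node, "year": int(year)}
            for base_col, event_col in layers:
                if scenario.baseline_redraw_each_year:
                    base = max(
                        1, int(round(rng.lognormal(mu_log, scenario.baseline_sigma)))
                    )
                else:
                    base = fixed_base[(node, base_col)]
                events = int(rng.poisson(rate * base))
                attempts = 0
                while events > base and attempts < 100:
                    events = int(rng.poisson(rate * base))
                    attempts += 1
                if events > base:
                    logger.warning(
                        "county %s year %d: event draw capped at baseline %d",
                        node, year, base,
                    )
                    events = base
                row[base_col] = base
                row[event_col] = events
            records.append(row)
    return CountTable(pd.DataFrame.from_records(records))


def generate_covariates(
    graph: CountyGraph,
    cluster_members: Sequence[str],
    covariate_effects: Mapping[str, tuple[float, float, float]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Normal covariates with inside/outside means, clipped to valid ranges."""
    nodes = graph.nodes
    inside = np.array([n in set(cluster_members) for n in nodes])
    data: dict[str, np.ndarray] = {}
    for col in COVARIATE_COLUMNS:
        outside_mean, inside_mean, sd = covariate_effects.get(
            col, DEFAULT_COVARIATE_EFFECTS[col]
        )
        means = np.where(inside, inside_mean, outside_mean)
        draws = rng.normal(means, sd)
        if col.startswith("pct_"):
            draws = np.clip(draws, 0.0, 100.0)
        else:
            draws = np.round(np.clip(draws, 0.0, None))
        data[col] = draws
    return pd.DataFrame(data, index=pd.Index(nodes, name="county"))


def generate_providers(
    graph: CountyGraph,
    table: CountTable,
    scenario: SyntheticScenario,
    rng: np.random.Generator,
    year: int | None = None,
) -> pd.DataFrame:
    """Split county totals across providers (Dirichlet-multinomial shares).

    Opioid counts are distributed over providers by a multivariate
    hypergeometric draw against the provider totals, which preserves both
    the county sums and the per-provider opioid <= total constraint.
    """
    year = int(scenario.years[-1] if year is None else year)
    k = scenario.n_providers_per_county
    if k < 1:
        raise ValueError("n_providers_per_county must be >= 1")
    names = [s for s, _ in scenario.specialties]
    probs = np.array([p for _, p in scenario.specialties], dtype=float)
    probs = probs / probs.sum()
    records = []
    for county in graph.nodes:
        row = table.df.loc[(county, year)]
        # one share vector per county: a provider's practice size drives
        # both its beneficiary and claim volumes
        shares = rng.dirichlet(np.ones(k))
        tot_b = rng.multinomial(int(row["total_beneficiaries"]), shares)
        op_b = rng.multivariate_hypergeometric(tot_b, int(row["opioid_beneficiaries"]))
        tot_p = rng.multinomial(int(row["total_claims"]), shares)
        op_p = rng.multivariate_hypergeometric(tot_p, int(row["opioid_claims"]))
        specs = rng.choice(len(names), size=k, p=probs)
        for j in range(k):
            records.append(
                {
                    "provider_id": f"{county}-P{j:02d}",
                    "county": county,
                    "specialty": names[int(specs[j])],
                    "total_beneficiaries": int(tot_b[j]),
                    "opioid_beneficiaries": int(op_b[j]),
                    "total_claims": int(tot_p[j]),
                    "opioid_claims": int(op_p[j]),
                }
            )
    return pd.DataFrame.from_records(records, columns=list(PROVIDER_COLUMNS))


def simulate(scenario: SyntheticScenario) -> SimulatedData:
    """Generate the full bundle from one scenario seed.

    Independent child RNG streams drive cluster placement, counts,
    covariates and providers, so e.g. changing the provider layer never
    perturbs the counts.
    """
    ss = np.random.SeedSequence(scenario.seed)
    rng_cluster, rng_counts, rng_cov, rng_prov = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    graph = make_grid_graph(scenario.rows, scenario.cols)
    if scenario.cluster_members is not None:
        cluster = tuple(sorted(scenario.cluster_members))
        if not graph.is_connected_subset(cluster):
            raise ValueError("configured cluster_members are not connected")
    else:
        cluster = random_connected_subset(graph, scenario.cluster_size, rng_cluster)
    tc = scenario.temporal_change
    temporal: tuple[str, ...] = ()
    if tc is not None:
        if tc.members is not None:
            temporal = tuple(sorted(tc.members))
            if not graph.is_connected_subset(temporal):
                raise ValueError("temporal_change members are not connected")
        else:
            temporal = random_connected_subset(
                graph, tc.size, rng_cluster, exclude=cluster
            )
    counts = generate_counts(graph, scenario, cluster, rng_counts, temporal)
    covariates = generate_covariates(
        graph, cluster, scenario.covariate_effects, rng_cov
    )
    providers = generate_providers(graph, counts, scenario, rng_prov)
    return SimulatedData(
        graph=graph,
        counts=counts,
        covariates=covariates,
        providers=providers,
        cluster_members=cluster,
        temporal_members=temporal,
        scenario=scenario,
    )
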