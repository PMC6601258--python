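"""Monte Carlo significance for scanned clusters.

The observed maximum score is ranked within the distribution of maximum
scores obtained on replicate datasets drawn under the null hypothesis:

* Kulldorff statistic: replicates keep every baseline fixed and
  redistribute the year's total event count across counties with a single
  multinomial draw with probabilities proportional to the baselines —
  i.e. independent Poisson(mu * baseline_i) counts conditioned on their
  observed total.
* Expectation-based statistic: the null fixes each county's mean at its
  history-derived expectation, so replicates draw independent
  Poisson(expected_i) counts per county with no conditioning on the total.

The add-one estimator p = (1 + #{replicate max >= observed}) / (R + 1)
never returns 0.  Every cluster in a ranked list — primary and secondary —
is compared against the same null distribution of maxima, the standard
conservative convention.  Replicate r draws from a child RNG stream spawned
deterministically from the root seed, so results do not depend on
evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._core import KULLDORFF
from .counts import CountTable
from .graph import CountyGraph
from .search import Cluster, ScanData, SearchConfig, _core_search, build_scan_data


@dataclass(frozen=True)
class NullDistribution:
    """Maximum scores of the search on R null replicates."""

    replicate_max_scores: np.ndarray
    seed: int
    statistic: str
    count_kind: str

    @property
    def n_replicates(self) -> int:
        return int(self.replicate_max_scores.size)

    def p_value(self, observed_score: float) -> float:
        r = self.n_replicates
        return (1.0 + int(np.sum(self.replicate_max_scores >= observed_score))) / (r + 1.0)


def simulate_null_replicate(
    table: CountTable, year: int, count_kind: str, rng: np.random.Generator
) -> CountTable:
    """One conditional null replicate of a year's event counts.

    Baselines are untouched; the year's total event count is redistributed
    across counties by one multinomial draw with probabilities
    baseline_i / total_baseline.  Counties with zero baseline therefore
    receive zero events in every replicate.
    """
    counties = sorted(table.df.xs(year, level="year").index)
    ev, base = table.arrays(counties, year, count_kind)
    total_base = base.sum()
    if total_base <= 0:
        raise ValueError("total baseline is zero; null model undefined")
    probs = base / total_base
    new_events = rng.multinomial(int(ev.sum()), probs)
    return table.with_events(year, count_kind, counties, new_events)


def _replicate_events(data: ScanData, rng: np.random.Generator) -> np.ndarray:
    if data.kind == KULLDORFF:
        probs = data.baselines / data.total_baseline
        return rng.multinomial(int(round(data.total_event)), probs).astype(np.float64)
    return rng.poisson(data.baselines).astype(np.float64)


def null_distribution(
    graph: CountyGraph,
    table: CountTable,
    year: int,
    config: SearchConfig,
    n_replicates: int = 999,
    seed: int | None = None,
) -> NullDistribution:
    """Run the same cluster search on ``n_replicates`` null datasets."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    root = config.seed if seed is None else seed
    data = build_scan_data(graph, table, year, config)
    active = np.ones(len(data.nodes), dtype=np.uint8)
    children = np.random.SeedSequence(root).spawn(n_replicates)
    maxima = np.empty(n_replicates, dtype=np.float64)
    for r in range(n_replicates):
        rng = np.random.default_rng(children[r])
        events_r = _replicate_events(data, rng)
        data_r = replace(data, events=events_r)
        maxima[r], _ = _core_search(data_r, config, active)
    return NullDistribution(
        replicate_max_scores=maxima,
        seed=root,
        statistic=config.statistic,
        count_kind=config.count_kind,
    )


def monte_carlo_pvalue(
    observed_score: float,
    graph: CountyGraph,
    table: CountTable,
    year: int,
    config: SearchConfig,
    n_replicates: int = 999,
    seed: int | None = None,
) -> tuple[float, NullDistribution]:
    """p-value of an observed maximum score against fresh null replicates."""
    if observed_score < 0:
        raise ValueError("observed score must be nonnegative")
    null = null_distribution(graph, table, year, config, n_replicates, seed)
    return null.p_value(observed_score), null


def mark_significant(
    clusters: Sequence[Cluster], null: NullDistribution, alpha: float = 0.05
) -> list[Cluster]:
    """Attach p-values (shared null of maxima) and flag p <= alpha."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    out = []
    for cl in clusters:
        p = null.p_value(cl.score.log_likelihood_ratio)
        out.append(replace(cl, p_value=p, significant=bool(p <= alpha)))
    return out
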