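"""End-to-end orchestration: load -> scan -> significance -> characterize.

Every run writes deterministic artifacts (cluster list CSV, null score CSV,
regression CSV, provider profile CSV) plus a metadata JSON echoing the
effective configuration and every convention in force, so a run can be
audited and reproduced byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import characterize as chz
from .counts import CountTable, MissingCountsError
from .graph import CountyGraph, graph_from_boundaries, load_adjacency
from .search import Cluster, SearchConfig, top_k_clusters
from .significance import NullDistribution, mark_significant, null_distribution
from .statistics import CONTINUITY_CONSTANT, ScoreValue

logger = logging.getLogger(__name__)

CLUSTER_CSV_COLUMNS = (
    "rank", "statistic", "count_kind", "year", "score",
    "p_value", "significant", "n_members", "members",
)

STATISTIC_ALIASES = {
    "kulldorff": "kulldorff_poisson",
    "kulldorff_poisson": "kulldorff_poisson",
    "expectation": "expectation_poisson",
    "expectation_poisson": "expectation_poisson",
}


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one scan run."""

    out: str
    counts: str | None = None
    adjacency: str | None = None
    boundaries: str | None = None
    contiguity: str = "rook"
    covariates: str | None = None
    providers: str | None = None
    statistic: str = "kulldorff_poisson"
    count_kind: str = "claims"
    year: int = 2015
    history_years: tuple[int, ...] = ()
    max_size: int = 30
    n_secondary: int = 1
    replicates: int = 999
    alpha: float = 0.05
    seed: int = 0
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.year in self.history_years:
            raise ValueError("year must not appear in history_years")
        if self.adjacency is not None and self.boundaries is not None:
            raise ValueError("give adjacency or boundaries, not both")
        object.__setattr__(
            self, "statistic", STATISTIC_ALIASES.get(self.statistic, self.statistic)
        )

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            statistic=self.statistic,
            count_kind=self.count_kind,
            max_size=self.max_size,
            n_secondary=self.n_secondary,
            seed=self.seed,
            history_years=tuple(int(y) for y in self.history_years),
        )


def _load_graph(config: RunConfig) -> CountyGraph:
    if config.adjacency is not None:
        return load_adjacency(config.adjacency)
    if config.boundaries is None:
        raise ValueError("scan requires an adjacency edge list or boundaries")
    return graph_from_boundaries(config.boundaries, contiguity=config.contiguity)


def _load_counts(config: RunConfig, graph: CountyGraph) -> CountTable:
    if config.counts is None:
        raise ValueError("scan requires a counts table")
    table = CountTable.from_csv(config.counts)
    needed_years = [config.year, *config.history_years]
    missing = [
        (c, y)
        for y in needed_years
        for c in graph.nodes
        if (c, y) not in table.df.index
    ]
    if missing:
        if not config.allow_missing:
            raise MissingCountsError(missing)
        table = table.zero_filled(graph.nodes, needed_years)
    return table


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        rows.append(
            {
                "rank": cl.rank,
                "statistic": cl.statistic,
                "count_kind": cl.count_kind,
                "year": cl.year,
                "score": cl.score.log_likelihood_ratio,
                "p_value": cl.p_value,
                "significant": cl.significant,
                "n_members": len(cl.members),
                "members": ";".join(cl.members),
            }
        )
    return pd.DataFrame(rows, columns=list(CLUSTER_CSV_COLUMNS))


def clusters_from_csv(path: str | Path) -> list[Cluster]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        members = tuple(str(row["members"]).split(";")) if row["n_members"] else ()
        score = float(row["score"])
        out.append(
            Cluster(
                members=members,
                score=ScoreValue(score, bool(score > 0)),
                statistic=str(row["statistic"]),
                count_kind=str(row["count_kind"]),
                year=int(row["year"]),
                rank=int(row["rank"]),
                p_value=None if pd.isna(row["p_value"]) else float(row["p_value"]),
                significant=None
                if pd.isna(row["significant"])
                else bool(row["significant"]),
            )
        )
    return out


def run_scan(config: RunConfig) -> tuple[list[Cluster], NullDistribution]:
    """Execute load -> search -> Monte Carlo -> significance; write artifacts."""
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    graph = _load_graph(config)
    table = _load_counts(config, graph)
    sconf = config.search_config()
    clusters = top_k_clusters(graph, table, config.year, sconf)
    null = null_distribution(
        graph, table, config.year, sconf,
        n_replicates=config.replicates, seed=config.seed,
    )
    clusters = mark_significant(clusters, null, alpha=config.alpha)

    clusters_to_frame(clusters).to_csv(
        out_dir / "clusters.csv", index=False, float_format="%.10g"
    )
    pd.DataFrame(
        {
            "replicate": np.arange(null.n_replicates),
            "score": null.replicate_max_scores,
        }
    ).to_csv(out_dir / "null_distribution.csv", index=False, float_format="%.10g")
    metadata = {
        "config": {
            "counts": config.counts,
            "adjacency": config.adjacency,
            "boundaries": config.boundaries,
            "contiguity": config.contiguity,
            "statistic": config.statistic,
            "count_kind": config.count_kind,
            "year": config.year,
            "history_years": list(config.history_years),
            "max_size": config.max_size,
            "n_secondary": config.n_secondary,
            "replicates": config.replicates,
            "alpha": config.alpha,
            "seed": config.seed,
            "allow_missing": config.allow_missing,
        },
        "conventions": {
            "score_scale": "log likelihood ratio (nats), one-sided high-rate",
            "tie_break": "lexicographically smallest sorted member list",
            "secondary_clusters": "disjoint removal; shared null of maxima",
            "expectation_baseline": "mean of history_years event counts, "
            f"floored at {CONTINUITY_CONSTANT}",
            "null_model": "multinomial conditioned on total events (kulldorff); "
            "independent Poisson(expected) (expectation)",
            "p_value": "(1 + #{replicate max >= observed}) / (R + 1)",
        },
    }
    (out_dir / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True) + "\n"
    )
    return clusters, null


def run_characterize(
    config: RunConfig, clusters_csv: str | Path | None = None
) -> tuple[chz.RegressionResult | None, pd.DataFrame | None]:
    """Label counties from significant clusters, run the stepwise logistic
    regression, and profile top-decile providers of the rank-1 cluster."""
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    if clusters_csv is None:
        clusters_csv = out_dir / "clusters.csv"
    clusters = clusters_from_csv(clusters_csv)
    significant = [cl for cl in clusters if cl.significant]

    result: chz.RegressionResult | None = None
    if config.covariates is None:
        raise ValueError("characterize requires a covariates table")
    covariates = chz.validate_covariates(pd.read_csv(Path(config.covariates)))
    reg_path = out_dir / "regression.csv"
    if not significant:
        logger.info("no significant clusters: regression skipped")
        pd.DataFrame(
            columns=["year", "count_kind", "variable", "odds_ratio", "p_value", "selected"]
        ).to_csv(reg_path, index=False)
    else:
        labels = chz.label_counties(list(covariates.index), significant)
        pruned = chz.prune_correlated(covariates, threshold=0.6)
        result = chz.stepwise_aic_logistic(
            labels, pruned, year=config.year, count_kind=config.count_kind
        )
        result.to_frame(list(pruned.columns)).to_csv(
            reg_path, index=False, float_format="%.10g"
        )

    profile: pd.DataFrame | None = None
    if config.providers is not None and significant:
        providers = pd.read_csv(Path(config.providers), dtype={"county": str})
        top = chz.top_decile_providers(providers, significant[0])
        if top.empty:
            logger.warning("no providers in the rank-1 cluster; profile skipped")
        else:
            profile = chz.provider_profile(top)
            profile.to_csv(
                out_dir / "provider_profile.csv", index=False, float_format="%.10g"
            )
    return result, profile


def export_clusters_geojson(
    clusters: list[Cluster], boundaries: str | Path, out_path: str | Path
) -> None:
    """FeatureCollection of cluster counties with rank/score/p properties."""
    with open(boundaries, encoding="utf-8") as fh:
        doc = json.load(fh)
    by_county = {
        f.get("properties", {}).get("county"): f for f in doc.get("features", [])
    }
    features = []
    for cl in clusters:
        for county in cl.members:
            feat = by_county.get(county)
            if feat is None:
                continue
            features.append(
                {
                    "type": "Feature",
                    "geometry": feat["geometry"],
                    "properties": {
                        "county": county,
                        "rank": cl.rank,
                        "score": cl.score.log_likelihood_ratio,
                        "p_value": cl.p_value,
                    },
                }
            )
    Path(out_path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )
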