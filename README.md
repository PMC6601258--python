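# graphscan

Network scan statistics for county-level prescription-drug surveillance.

`graphscan` detects geographic hot spots of opioid prescribing in
county-level claims data.  Instead of the classic circular windows, it
searches over county sets that induce a **connected subgraph** of the
county contiguity graph, so detected clusters can follow valleys,
highway corridors, and other irregular shapes.  The package provides the
full analysis chain:

1. **Cluster detection** — Kulldorff's Poisson scan statistic, maximised
   over connected clusters of bounded size, with an exact enumeration
   oracle on small graphs, a greedy + local-search heuristic at state
   scale, and a circular-window baseline for comparison.
2. **Temporal change detection** — an expectation-based Poisson scan that
   compares each county's current counts against its own recent history,
   flagging regions whose counts grew faster than expected.
3. **Significance** — Monte Carlo replication under the null (events
   redistributed proportionally to baselines, conditioned on the total),
   with the add-one p-value estimator.
4. **Characterization** — logistic regression of cluster membership on
   county demographics (correlation pruning at |r| ≥ 0.6, stepwise-AIC
   selection in both directions, odds ratios with Wald p-values), plus
   extraction and specialty profiling of top-decile prescribers inside
   the detected clusters.
5. **Synthetic data** — a generator that emulates the statistical
   structure of county/provider claims tables, so the whole pipeline is
   testable without access to restricted data.

It is aimed at epidemiologists and health-services researchers who work
with aggregated prescription counts (e.g. public prescriber-level
summaries) and ACS-style county demographics.

## The statistics

For county *i*, let `tot(i)` be the baseline count (total claims or total
beneficiaries) and `opi(i)` the event count (opioid claims or opioid
beneficiaries).  Under the null, `opi(i) ~ Poisson(mu * tot(i))` with a
single statewide rate `mu = opi(all) / tot(all)`.  Under the alternative
for a cluster C, counties inside C have rate `eta > mu`.  With
`c = opi(C)`, `b = tot(C)`, totals `C_tot`, `B_tot`, and
`E = C_tot * b / B_tot`, the profile log likelihood ratio is

    log F(C) = c·ln(c/E) + (C_tot − c)·ln((C_tot − c)/(C_tot − E))   if c > E, else 0.

The expectation-based statistic compares a county's (or cluster's)
current count `c` against its expectation `b` built from past years
(mean of the history years), profiling a fold-change `mu ≥ 1`:

    score = c·ln(c/b) + b − c   if c > b, else 0.

Both are one-sided (high-rate) statistics reported in nats.  The
searched family is every connected subgraph of the contiguity graph up
to a configurable size (default 30 counties); significance is assessed
against the distribution of the *maximum* score on null replicates.

## Worked example

Generate a synthetic state (8×8 county lattice, background opioid rate
0.1, one planted 6-county cluster at rate 0.2), scan it, and
characterize the result:

```bash
graphscan simulate --rows 8 --cols 8 --eta 0.2 --seed 7 --out demo/sim
graphscan scan --counts demo/sim/counts.csv --adjacency demo/sim/adjacency.csv \
    --statistic kulldorff --count-kind claims --year 2015 \
    --max-size 10 --replicates 999 --alpha 0.05 --seed 42 --out demo/run
```

prints

```
rank 1: 6 counties, score 1248.812, p=0.001 (significant)
rank 2: 2 counties, score 0.905, p=1 (not significant)
```

The rank-1 cluster is exactly the planted one (`scenario.json` records
the truth: `c01x02 c02x02 c02x03 c03x02 c03x03 c03x04`): its log
likelihood-ratio score, 1248.8, exceeded the maximum score of all 999
null replicates, so the Monte Carlo p-value takes its smallest possible
value 1/1000.  The rank-2 cluster is ordinary Poisson noise (p = 1).
Characterization then labels the 6 cluster counties 1 and the other 58
counties 0 and runs the pruned stepwise-AIC logistic regression; with
the default (no demographic effect) generator it selects the
intercept-only model, and it profiles the top-decile prescribers of the
cluster by specialty:

```bash
graphscan characterize --clusters demo/run/clusters.csv \
    --covariates demo/sim/covariates.csv --providers demo/sim/providers.csv \
    --year 2015 --count-kind claims --out demo/run
graphscan report --run demo/run
```

Real data drop in the same way: a counts CSV
(`county,year,total_beneficiaries,opioid_beneficiaries,total_claims,opioid_claims`),
an adjacency edge list (`county_a,county_b`) or a GeoJSON boundary file
(rook or queen contiguity), a covariates CSV, and a provider CSV.  All
artifacts (cluster list, null-score distribution, regression table,
provider profile, run metadata) are deterministic functions of the
inputs and the seed.

## Layout

```
src/graphscan/
  graph.py         county contiguity graphs (edge lists, GeoJSON, rook/queen)
  counts.py        validated (county, year) count tables, cluster aggregation
  statistics.py    Kulldorff Poisson and expectation-based Poisson scores
  search.py        exact enumeration, greedy+swap heuristic, top-k, circular baseline
  _core.py         numba-compiled search inner loops
  significance.py  conditional null replicates, Monte Carlo p-values
  characterize.py  labels, pruning, stepwise-AIC logistic regression, providers
  synthetic.py     scenario generator (counts, covariates, providers)
  pipeline.py      end-to-end runs with deterministic artifacts
  cli.py           `graphscan simulate|scan|characterize|report`
docs/methods.md    model, assumptions, conventions, limitations
```
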