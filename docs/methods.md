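# Methods

This note documents the models, conventions and design choices behind
`graphscan`, and what the simulation results do and do not establish.

## Data model

The unit of analysis is the county-year.  Each row carries two baseline
counts (total beneficiaries, total prescription claims) and two event
counts (opioid beneficiaries, opioid claims).  The two *count kinds* —
`beneficiary` and `claims` — are analysed separately with identical
machinery; a beneficiary-based cluster and a claims-based cluster over
the same counties are distinct results.  County identifiers are opaque
strings; independent cities and other non-county units are ordinary
nodes.  Counts must be nonnegative integers with events ≤ baselines per
row; violations abort before any computation.

Counties present in the contiguity graph but absent from the count table
are an error by default.  With `allow_missing` they are zero-filled with
a logged warning — the convention for public files that suppress small
cells.  Zero-filled counties can never raise a cluster's score (they add
baseline but no events), so the choice is conservative.

## Contiguity graph

Two counties are adjacent when they share a boundary.  From polygon
boundaries the default rule is **rook** (shared segment of positive
length), reading "share a boundary" literally; **queen** (any shared
point, including corners) is available by flag.  The choice is recorded
in run metadata.  Polygon layers that overlap with positive area are
treated as adjacent under both rules.  Graphs may be disconnected; the
search operates per connected component automatically because greedy
growth cannot cross component boundaries.

## Scan statistics

Both statistics are one-sided high-rate profile log likelihood ratios in
nats.  Working on the log scale is monotone-equivalent to the raw
likelihood ratio and necessary in practice: at realistic count
magnitudes the raw ratio overflows double precision.

**Kulldorff Poisson.**  With cluster events `c`, cluster baseline `b`,
roster totals `C_tot`, `B_tot` and `E = C_tot·b/B_tot`:

    log F(C) = c·ln(c/E) + (C_tot−c)·ln((C_tot−c)/(C_tot−E)),  c > E
             = 0 otherwise,

with the convention `0·ln(0/x) = 0` (a cluster holding all events stays
finite).  This is the likelihood ratio profiled at `eta = c/b` inside and
`mu = (C_tot−c)/(B_tot−b)` outside; the closed form is verified against
direct numeric maximisation of the two Poisson likelihoods in the test
suite and the acceptance script (agreement to ~1e-9 on random counts).

**Expectation-based Poisson.**  A county's expectation for the target
year is the arithmetic mean of its event counts over the supplied
history years.  The paper-style single-previous-year baseline is the
special case of a one-year history; the mean-of-all-years default covers
multi-year averaging, and the years used are echoed into run metadata.
For a region, `score = c·ln(c/b) + b − c` when `c > b`, else 0 (the
fold-change `mu ≥ 1` profiled out).  Expected counts below the
**continuity constant 0.5** are floored at it, with a logged warning:
a zero expectation would make any nonzero count infinitely surprising,
which is an artifact of sparse histories, not evidence.

## Cluster search

The search space is every county set that induces a connected subgraph,
of size 1 to `max_size`.  `max_size` defaults to 30 — the scale of the
largest cluster this kind of analysis is expected to report at state
level — and is configurable.

* **Exact oracle** (`exact_best_cluster`): enumerates every connected
  subset exactly once (rooted at each subset's minimum node, extension
  through exclusive neighbourhoods) and takes the argmax.  It refuses
  graphs above a node budget (default 16) rather than run for hours.
* **Heuristic** (`search_best_cluster`): from every node as seed,
  greedily add the adjacent county that maximises the statistic, keep
  the best prefix of the growth path, then run a 1-swap local search
  (drop one member / add one neighbour while connectivity holds,
  accepting strict improvements to a fixed point); the best candidate
  over all seeds wins.  The local search runs per seed.  The heuristic's
  adequacy is enforced empirically: on random instances small enough to
  enumerate it must attain the exact optimum (it does, on all tested
  instances), not assumed from the algorithm's construction.
* **Tie-breaking** is lexicographic on the sorted member list at every
  level (candidate scans in ascending node order with strict-improvement
  updates), so all results are deterministic.
* **Secondary clusters** (`top_k_clusters`): find the best cluster,
  remove its counties from the graph, repeat.  This yields pairwise
  disjoint clusters with nonincreasing scores.  The roster totals
  (`C_tot`, `B_tot`, hence the statewide rate) are kept at their
  full-roster values throughout: the statewide rate is a property of
  the state, not of the counties that survive removal.
* **Circular baseline** (`circular_scan`): the classic distance-based
  scan for comparison.  Zones are a centre county plus its k nearest
  counties by great-circle centroid distance, grown while the zone
  baseline stays within `max_baseline_fraction` (default 0.5, the common
  convention) of the total.  Zones need not be graph-connected, and on
  lattice geometries every circular zone is connected, which makes the
  connected-subgraph family a superset there — the basis for the
  dominance check in the tests.

The inner search loop is compiled with numba over CSR adjacency arrays
because Monte Carlo significance re-runs it hundreds of times per
analysis and tens of thousands of times in the calibration experiments.

## Monte Carlo significance

For the Kulldorff statistic, null replicates keep all baselines fixed
and redistribute the year's total event count across counties with one
multinomial draw with probabilities proportional to baselines —
independent Poisson counts conditioned on their observed total.  For the
expectation-based statistic the null fixes each county's mean at its
history-derived expectation, so replicates draw independent
Poisson(expected) counts with no conditioning; the two conventions are
recorded in run metadata.

Each replicate is searched with the same algorithm and configuration as
the observed data, and the p-value is the add-one estimator
`p = (1 + #{replicate max ≥ observed}) / (R + 1)`, which is never zero
and has resolution 1/(R+1).  The default is R = 999 (round p
granularity of 1/1000); any R, including 1000, is a flag away.  Every
cluster in a ranked list — primary and secondary — is compared against
the same null distribution of maxima.  This is the standard conservative
convention for secondary clusters; a fresh conditional null per rank is
not attempted.  Replicate r draws from a child RNG stream spawned
deterministically from the root seed, so results are independent of
evaluation order and bit-reproducible.

Calibration is checked by simulation rather than assumed: on 200 null
datasets (6×6 lattice, rate 0.1, mean baseline 2000, R = 199) the
rejection rate at α = 0.05 must fall inside the exact binomial 95%
interval around 0.05.  The observed rate sits slightly below 0.05,
consistent with the conservatism of conditioning on totals when the
generative null also randomises baselines.

## Characterization

Counties are labelled 1 if they belong to any significant cluster of the
configured statistic, count kind and year, else 0.  Candidate covariates
are the eight county demographics declared in the covariate schema
(percent African American, percent American Indian, percent male,
housing units, percent Medicaid, percent Medicare, percent
direct-purchase insurance, percent of households below half the poverty
threshold).  Pruning scans them in that declared order and drops any
column whose absolute Pearson correlation with an already-kept column
reaches 0.6, so the surviving set always satisfies max |r| < 0.6; the
order is fixed because "keep one of each correlated group" is otherwise
underdetermined.  Zero-variance columns are dropped with a warning.

The logistic regression starts from the full pruned model and moves
stepwise in both directions, applying whichever single-column addition
or deletion lowers the AIC most, while the AIC strictly decreases — the
same procedure as R's `stepAIC(direction="both")`.  On simulated
instances the selected model always matches exhaustive minimisation of
the AIC over all 2^k subsets (k ≤ 8).  Coefficients are reported as odds
ratios `exp(beta)` with Wald p-values; p < 0.1 flags a variable as
significant.  Perfect separation is detected (via the fitter's
separation diagnostics and non-finite coefficients) and raised as an
error naming the suspect variable rather than reported as an absurd
odds ratio.  Regressions run separately per year and count kind.

Provider profiling restricts the provider table to a cluster's counties
and keeps providers at or above the 90th percentile of **both** opioid
beneficiary and opioid claim counts.  The percentile uses the `higher`
interpolation with ties inclusive, so with n distinct values exactly
⌈n/10⌉ providers qualify — with 10 strictly increasing providers, the
top one.  The retained subset is summarised per specialty: provider
count, mean percent opioid beneficiaries, mean percent opioid claims,
mean total beneficiaries, sorted by provider count.  Providers with zero
totals carry no percentage and are excluded with a warning.

## Synthetic data

The generator emulates the joint structure the analysis assumes, not any
particular state's numbers:

* **Baselines** are log-normal (county sizes are right-skewed), mean
  5000 and log-sd 0.5 by default, rounded with a floor of 1.  By default
  each county's baseline is drawn once and held fixed across years —
  county populations persist, so year-over-year event changes reflect
  rates; `baseline_redraw_each_year` re-draws them independently when
  size churn itself is the object of study.
* **Events** are Poisson with rate `mu` outside and `eta ≥ mu` inside
  one connected cluster (random-walk-grown when not given explicitly);
  an optional temporal change multiplies a second, disjoint region's
  rate in one stated year only.  Draws exceeding the baseline are
  resampled and finally capped with a warning (only relevant at rates
  near 1).  `eta = mu` is the null scenario.
* **Covariates** are normal with separate inside/outside means per
  column, clipped to [0, 100] for percentages; default means approximate
  mid-Atlantic county demographics with no inside/outside difference.
* **Providers** split each county's totals by a symmetric Dirichlet
  share vector; one share vector per county drives both the beneficiary
  and the claims layer, because a provider's practice size drives both
  volumes.  Opioid counts are distributed over providers by a
  multivariate hypergeometric draw against provider totals, which
  preserves county sums exactly and the per-provider opioid ≤ total
  constraint.  Specialties are drawn i.i.d. from a configurable list.

What the generator does **not** emulate: small-cell suppression and
top-coding of public count files, ACS sampling error, spatial
autocorrelation of demographics, provider turnover between years, and
rate gradients (the planted cluster has a sharp boundary).  Passing the
simulation experiments therefore shows the machinery is correct and
calibrated under the stated model; it does not show that real opioid
clusters have sharp boundaries or that real demographics are spatially
independent.

## Experiment scales

The calibration and recovery experiments use 6×6 to 10×10 lattices, 199
null replicates per dataset, 50–200 datasets per experiment, and 100
regression simulations at 500 counties; these sizes give binomial/Monte
Carlo error bars comfortably inside the asserted bounds while keeping
the full suite and the acceptance script in the minutes range on one
CPU.  The temporal-discrimination scenario plants a persistent cluster
at 3× the background rate alongside a disjoint region that doubles only
in the final year: the Kulldorff scan on the final year alone reports
the persistent cluster, while the expectation-based scan, whose
baseline is each county's own 2-year history, reports the changed
region — the two statistics answer different questions by construction.

## Known limitations

* The heuristic search carries no optimality guarantee at state scale;
  its exactness is verified only up to the enumeration budget.
* The logistic characterization ignores spatial correlation among
  counties; standard errors are valid under independence only.
* The circular baseline implements circles only (no ellipses, no
  space-time cylinders).
* The expectation-based statistic conditions on history as fixed truth;
  a county with an anomalously low history year inflates its apparent
  change.
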