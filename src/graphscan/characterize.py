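"""Characterization of anomalous counties and providers.

Counties are labelled 1 when they belong to a significant cluster and 0
otherwise, and the label is regressed on county demographics with a
logistic model.  Candidate covariates are first pruned so that no pair
retains an absolute Pearson correlation at or above the threshold
(multicollinearity inflates coefficient standard errors), then a stepwise
search in both directions minimises the AIC.  Coefficients are reported as
odds ratios exp(beta) with Wald p-values; p < 0.1 flags a variable as
significant.

The provider layer mirrors public per-prescriber count files: within a
cluster's counties, providers in the top decile of both opioid beneficiary
and opioid claim counts are extracted and profiled by specialty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .search import Cluster

logger = logging.getLogger(__name__)

#: declared candidate covariates, in pruning order
COVARIATE_COLUMNS = (
    "pct_african_american",
    "pct_american_indian",
    "pct_male",
    "n_housing_units",
    "pct_medicaid",
    "pct_medicare",
    "pct_direct_purchase",
    "pct_income_poverty_lt_0_5",
)

PROVIDER_COLUMNS = (
    "provider_id",
    "county",
    "specialty",
    "total_beneficiaries",
    "opioid_beneficiaries",
    "total_claims",
    "opioid_claims",
)

SIGNIFICANCE_P = 0.1


class CharacterizationError(ValueError):
    pass


class SeparationError(CharacterizationError):
    """Logistic MLE does not exist: a covariate separates the classes."""


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Check the covariate table: county index, declared columns, ranges."""
    frame = df.copy()
    if "county" in frame.columns:
        frame["county"] = frame["county"].astype(str)
        frame = frame.set_index("county")
    missing = [c for c in COVARIATE_COLUMNS if c not in frame.columns]
    if missing:
        raise CharacterizationError(f"missing covariate columns {missing}")
    frame = frame[list(COVARIATE_COLUMNS)].sort_index()
    if frame.index.duplicated().any():
        raise CharacterizationError("duplicate county rows in covariate table")
    pct_cols = [c for c in COVARIATE_COLUMNS if c.startswith("pct_")]
    if ((frame[pct_cols] < 0) | (frame[pct_cols] > 100)).any().any():
        raise CharacterizationError("percentage covariates must lie in [0, 100]")
    if (frame["n_housing_units"] < 0).any():
        raise CharacterizationError("counts must be nonnegative")
    return frame


def validate_providers(df: pd.DataFrame) -> pd.DataFrame:
    frame = df.copy()
    missing = [c for c in PROVIDER_COLUMNS if c not in frame.columns]
    if missing:
        raise CharacterizationError(f"missing provider columns {missing}")
    frame = frame[list(PROVIDER_COLUMNS)]
    counts = frame[list(PROVIDER_COLUMNS[3:])]
    if (counts < 0).any().any():
        raise CharacterizationError("provider counts must be nonnegative")
    if (frame["opioid_beneficiaries"] > frame["total_beneficiaries"]).any() or (
        frame["opioid_claims"] > frame["total_claims"]
    ).any():
        raise CharacterizationError("opioid counts exceed totals for some providers")
    return frame


# ---------------------------------------------------------------------------
# county labelling and regression

def label_counties(
    all_counties: Sequence[str], significant_clusters: Iterable[Cluster]
) -> pd.Series:
    """0/1 label per county: 1 iff the county sits in a significant cluster."""
    roster = [str(c) for c in all_counties]
    roster_set = set(roster)
    anomalous: set[str] = set()
    for cl in significant_clusters:
        unknown = set(cl.members) - roster_set
        if unknown:
            raise CharacterizationError(
                f"cluster members outside county roster: {sorted(unknown)[:5]}"
            )
        anomalous.update(cl.members)
    return pd.Series(
        [1 if c in anomalous else 0 for c in roster], index=roster, name="anomalous"
    )


def prune_correlated(covariates: pd.DataFrame, threshold: float = 0.6) -> pd.DataFrame:
    """Greedy decorrelation in declared column order.

    A column is dropped when its absolute Pearson correlation with any
    already-kept column reaches the threshold; every surviving pair then
    satisfies |r| < threshold.  Zero-variance columns are dropped with a
    warning (their correlation is undefined).
    """
    if not (0 < threshold <= 1):
        raise CharacterizationError("threshold must lie in (0, 1]")
    if len(covariates) < 2:
        raise CharacterizationError("need at least 2 counties to measure correlation")
    kept: list[str] = []
    for col in covariates.columns:
        x = covariates[col].to_numpy(float)
        if np.std(x) == 0.0:
            logger.warning("covariate %s has zero variance; dropped", col)
            continue
        correlated = False
        for k in kept:
            r = np.corrcoef(x, covariates[k].to_numpy(float))[0, 1]
            if abs(r) >= threshold:
                logger.info("covariate %s dropped: |r|=%.3f with %s", col, abs(r), k)
                correlated = True
                break
        if not correlated:
            kept.append(col)
    return covariates[kept]


@dataclass(frozen=True)
class RegressionResult:
    """Stepwise-AIC logistic model summary on the odds-ratio scale."""

    selected_variables: tuple[str, ...]
    odds_ratios: dict[str, float]
    p_values: dict[str, float]
    intercept_odds_ratio: float
    intercept_p_value: float
    aic: float
    year: int | None = None
    count_kind: str | None = None

    def significant_variables(self, p: float = SIGNIFICANCE_P) -> tuple[str, ...]:
        return tuple(v for v in self.selected_variables if self.p_values[v] < p)

    def to_frame(self, candidates: Sequence[str]) -> pd.DataFrame:
        rows = [
            {
                "year": self.year,
                "count_kind": self.count_kind,
                "variable": "(intercept)",
                "odds_ratio": self.intercept_odds_ratio,
                "p_value": self.intercept_p_value,
                "selected": True,
            }
        ]
        for v in candidates:
            sel = v in self.selected_variables
            rows.append(
                {
                    "year": self.year,
                    "count_kind": self.count_kind,
                    "variable": v,
                    "odds_ratio": self.odds_ratios.get(v, np.nan),
                    "p_value": self.p_values.get(v, np.nan),
                    "selected": sel,
                }
            )
        return pd.DataFrame(rows)


def _fit_logit(y: np.ndarray, frame: pd.DataFrame, cols: Sequence[str]):
    X = sm.add_constant(frame[list(cols)], has_constant="add")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # Newton's Hessian goes singular near the boundary; retry with
            # a gradient-based fit before concluding the MLE does not exist
            try:
                with np.errstate(all="ignore"):
                    fit = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
            except Exception as exc:  # noqa: BLE001 - any failure means no MLE
                raise SeparationError(
                    f"logistic fit failed for columns {list(cols)}: {exc}"
                ) from exc
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        worst = max(cols, key=lambda v: abs(float(fit.params[v])), default="(intercept)")
        raise SeparationError(
            f"perfect separation detected; suspect variable: {worst}"
        )
    if not np.all(np.isfinite(fit.params)):
        raise SeparationError(f"non-finite coefficients for columns {list(cols)}")
    return fit


def stepwise_aic_logistic(
    labels: pd.Series,
    covariates: pd.DataFrame,
    year: int | None = None,
    count_kind: str | None = None,
) -> RegressionResult:
    """Bidirectional stepwise AIC selection over a logistic model.

    Starts from the full model; at each step evaluates every single-column
    drop and every single-column addition and applies the move with the
    lowest AIC, while the AIC strictly decreases.  Candidate moves are
    evaluated in declared column order, so ties resolve deterministically.
    """
    common = covariates.index.intersection(labels.index)
    if len(common) < len(covariates):
        raise CharacterizationError("labels missing for some covariate counties")
    y = labels.loc[covariates.index].to_numpy(float)
    classes = np.unique(y)
    if classes.size < 2:
        raise CharacterizationError(
            f"labels are single-class ({classes.tolist()}); regression undefined"
        )
    if covariates.shape[1] < 1:
        raise CharacterizationError("need at least one candidate covariate")
    cols = list(covariates.columns)

    cache: dict[tuple[str, ...], float] = {}

    def aic_of(subset: tuple[str, ...]) -> float:
        if subset not in cache:
            cache[subset] = float(_fit_logit(y, covariates, subset).aic)
        return cache[subset]

    current = tuple(cols)
    best_aic = aic_of(current)
    while True:
        moves: list[tuple[float, tuple[str, ...]]] = []
        for v in cols:
            if v in current:
                cand = tuple(c for c in current if c != v)
            else:
                cand = tuple(c for c in cols if c in current or c == v)
            moves.append((aic_of(cand), cand))
        best_move = min(moves, key=lambda t: t[0])
        if best_move[0] < best_aic - 1e-10:
            best_aic, current = best_move[0], best_move[1]
        else:
            break

    fit = _fit_logit(y, covariates, current)
    params = fit.params
    pvals = fit.pvalues
    return RegressionResult(
        selected_variables=current,
        odds_ratios={v: float(np.exp(params[v])) for v in current},
        p_values={v: float(pvals[v]) for v in current},
        intercept_odds_ratio=float(np.exp(params["const"])),
        intercept_p_value=float(pvals["const"]),
        aic=float(fit.aic),
        year=year,
        count_kind=count_kind,
    )


# ---------------------------------------------------------------------------
# provider profiling

def top_decile_providers(providers: pd.DataFrame, cluster: Cluster) -> pd.DataFrame:
    """Providers in a cluster's counties that sit in the top decile of both
    opioid beneficiary and opioid claim counts (nearest-rank 90th
    percentile, ties inclusive)."""
    providers = validate_providers(providers)
    inside = providers[providers["county"].astype(str).isin(cluster.members)]
    if inside.empty:
        logger.warning("no providers located in cluster counties; empty result")
        return inside
    # 'higher' interpolation: with n distinct values exactly ceil(n/10)
    # providers clear the threshold; ties at the threshold stay inclusive
    q_b = np.quantile(inside["opioid_beneficiaries"], 0.9, method="higher")
    q_p = np.quantile(inside["opioid_claims"], 0.9, method="higher")
    return inside[
        (inside["opioid_beneficiaries"] >= q_b) & (inside["opioid_claims"] >= q_p)
    ]


def provider_profile(subset: pd.DataFrame) -> pd.DataFrame:
    """Per-specialty summary of a provider subset.

    Columns: provider count, mean % opioid beneficiaries, mean % opioid
    claims, mean total beneficiaries; sorted by provider count descending.
    Providers with zero totals carry no percentage and are excluded.
    """
    if subset.empty:
        raise CharacterizationError("cannot profile an empty provider subset")
    subset = validate_providers(subset)
    zero = (subset["total_beneficiaries"] == 0) | (subset["total_claims"] == 0)
    if zero.any():
        logger.warning(
            "%d providers with zero totals excluded from specialty means", int(zero.sum())
        )
        subset = subset[~zero]
        if subset.empty:
            raise CharacterizationError("all providers had zero totals")
    work = subset.assign(
        pct_opioid_beneficiaries=100.0
        * subset["opioid_beneficiaries"]
        / subset["total_beneficiaries"],
        pct_opioid_claims=100.0 * subset["opioid_claims"] / subset["total_claims"],
    )
    prof = (
        work.groupby("specialty")
        .agg(
            n_providers=("provider_id", "size"),
            mean_pct_opioid_beneficiaries=("pct_opioid_beneficiaries", "mean"),
            mean_pct_opioid_claims=("pct_opioid_claims", "mean"),
            mean_total_beneficiaries=("total_beneficiaries", "mean"),
        )
        .sort_values(["n_providers", "specialty"], ascending=[False, True])
        .reset_index()
    )
    return prof
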