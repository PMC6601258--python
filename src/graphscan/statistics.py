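"""Poisson scan-statistic scores.

Two one-sided (high-rate) statistics are provided, both reported as log
likelihood ratios in nats:

* **Kulldorff Poisson.**  Under H0 the event count of county *i* is
  Poisson(mu * baseline_i) with a single statewide rate
  mu = total_events / total_baseline.  Under H1(C) counties inside the
  cluster C have rate eta and counties outside rate mu, with mu < eta.
  Profiling out (eta, mu) gives, with c = events in C, b = baseline in C,
  C_tot/B_tot the roster totals and E = C_tot * b / B_tot,

      log F(C) = c * ln(c/E) + (C_tot - c) * ln((C_tot - c)/(C_tot - E))

  when c > E, else 0 (the constrained maximum sits at eta = mu).

* **Expectation-based Poisson.**  The current count c of a region is
  compared with its own expectation b built from past years:
  H0: c ~ Poisson(b); H1: c ~ Poisson(mu * b) with fold-change mu > 1.
  Profiling mu >= 1 gives  c * ln(c/b) + b - c  when c > b, else 0.

Working on the log scale is monotone-equivalent to the raw likelihood
ratio and avoids overflow at realistic count magnitudes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .counts import ClusterCounts, CountTable, MissingCountsError

logger = logging.getLogger(__name__)

#: floor applied to nonpositive expected counts in the expectation-based
#: statistic; an expectation of exactly zero would make any nonzero count
#: infinitely surprising, which is an artifact of small samples.
CONTINUITY_CONSTANT = 0.5


class UndefinedRateError(ValueError):
    """Raised when a rate is requested with zero total baseline."""


class InvalidCountsError(ValueError):
    """Raised when counts admit no finite score (e.g. events with zero baseline)."""


@dataclass(frozen=True)
class ScoreValue:
    """A scan score: log likelihood ratio (nats) plus the high-rate flag."""

    log_likelihood_ratio: float
    high_rate: bool

    def __post_init__(self) -> None:
        if self.log_likelihood_ratio < 0:
            raise ValueError("log likelihood ratio must be nonnegative")
        if not self.high_rate and self.log_likelihood_ratio != 0.0:
            raise ValueError("score must be 0 when the cluster rate is not elevated")


def global_rate(cc: ClusterCounts) -> float:
    """Statewide event rate: total events per unit total baseline."""
    if cc.total_baseline <= 0:
        raise UndefinedRateError("total baseline is zero")
    return cc.total_event / cc.total_baseline


def kulldorff_poisson_score(cc: ClusterCounts) -> ScoreValue:
    """Kulldorff Poisson log likelihood ratio for one cluster (one-sided)."""
    c = float(cc.event)
    b = float(cc.baseline)
    c_tot = float(cc.total_event)
    b_tot = float(cc.total_baseline)
    if b <= 0 and c > 0:
        raise InvalidCountsError("events observed with zero cluster baseline")
    expected = c_tot * b / b_tot
    if c <= expected or c_tot <= 0:
        return ScoreValue(0.0, False)
    if expected <= 0:
        # unreachable when baseline > 0 and c_tot finite; guard anyway
        raise InvalidCountsError("zero expected events with positive observed events")
    score = c * math.log(c / expected)
    rem = c_tot - c
    if rem > 0:
        score += rem * math.log(rem / (c_tot - expected))
    return ScoreValue(score, True)


def expectation_poisson_score(
    current: float, expected: float, continuity: float = CONTINUITY_CONSTANT
) -> ScoreValue:
    """Expectation-based Poisson log likelihood ratio (fold-change mu >= 1)."""
    c = float(current)
    if c < 0:
        raise InvalidCountsError("negative event count")
    b = float(expected)
    if b <= 0:
        logger.warning(
            "nonpositive expected count %g floored at continuity constant %g",
            b, continuity,
        )
        b = continuity
    if c <= b:
        return ScoreValue(0.0, False)
    return ScoreValue(c * math.log(c / b) + b - c, True)


def expected_from_history(
    table: CountTable,
    county: str,
    target_year: int,
    history_years: Sequence[int],
    count_kind: str = "claims",
    continuity: float = CONTINUITY_CONSTANT,
) -> float:
    """Expected event count for ``target_year``: mean over the history years.

    The mean is floored at the continuity constant so zero histories do not
    produce unbounded scores.  Using the mean of all supplied history years
    covers both the single-previous-year convention and multi-year
    averaging; the caller records which years were used.
    """
    if not history_years:
        raise ValueError("history_years must be nonempty")
    if target_year in history_years:
        raise ValueError(f"target year {target_year} cannot be part of its history")
    keys = [(county, int(y)) for y in history_years]
    missing = [k for k in keys if k not in table.df.index]
    if missing:
        raise MissingCountsError(missing)
    _, event_col = _event_column(count_kind)
    mean = float(table.df.loc[keys, event_col].mean())
    if mean < continuity:
        logger.warning(
            "county %s: zero/low history mean %g floored at %g", county, mean, continuity
        )
        return continuity
    return mean


def _event_column(count_kind: str) -> tuple[str, str]:
    from .counts import _kind_columns

    return _kind_columns(count_kind)
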