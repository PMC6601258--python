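"""Per-county, per-year count tables and cluster aggregation.

Each row of a :class:`CountTable` holds, for one county and one year, the
baseline counts (total beneficiaries, total prescription claims) and the
event counts (opioid beneficiaries, opioid claims).  The scan statistics
operate on one *count kind* at a time: ``beneficiary`` pairs
``opioid_beneficiaries`` (events) with ``total_beneficiaries`` (baseline);
``claims`` pairs ``opioid_claims`` with ``total_claims``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COLUMNS = (
    "total_beneficiaries",
    "opioid_beneficiaries",
    "total_claims",
    "opioid_claims",
)

#: count kind -> (baseline column, event column)
COUNT_KINDS: dict[str, tuple[str, str]] = {
    "beneficiary": ("total_beneficiaries", "opioid_beneficiaries"),
    "claims": ("total_claims", "opioid_claims"),
}


class CountValidationError(ValueError):
    """Raised when a count table violates its invariants."""


class MissingCountsError(KeyError):
    """Raised when required (county, year) rows are absent."""

    def __init__(self, missing: Sequence[tuple[str, int]]):
        self.missing = list(missing)
        super().__init__(f"missing (county, year) rows: {self.missing[:10]}"
                         + (" ..." if len(self.missing) > 10 else ""))


@dataclass(frozen=True)
class ClusterCounts:
    """Event/baseline sums for a cluster together with the roster totals."""

    event: int
    baseline: int
    total_event: int
    total_baseline: int

    def __post_init__(self) -> None:
        if not (0 <= self.event <= self.total_event):
            raise CountValidationError(
                f"event {self.event} outside [0, total_event={self.total_event}]"
            )
        if not (0 <= self.baseline <= self.total_baseline):
            raise CountValidationError(
                f"baseline {self.baseline} outside [0, total_baseline={self.total_baseline}]"
            )
        if self.total_baseline <= 0:
            raise CountValidationError("total_baseline must be positive")


class CountTable:
    """Validated (county, year) count table backed by a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame):
        frame = df.copy()
        if not isinstance(frame.index, pd.MultiIndex):
            required = ["county", "year", *COUNT_COLUMNS]
            missing_cols = [c for c in required if c not in frame.columns]
            if missing_cols:
                raise CountValidationError(f"missing columns {missing_cols}")
            frame["county"] = frame["county"].astype(str)
            frame["year"] = frame["year"].astype(int)
            frame = frame.set_index(["county", "year"])
        frame = frame[list(COUNT_COLUMNS)].sort_index()
        if frame.index.duplicated().any():
            dups = frame.index[frame.index.duplicated()].tolist()
            raise CountValidationError(f"duplicate (county, year) keys: {dups[:5]}")
        vals = frame.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise CountValidationError("counts must be finite")
        if np.any(vals < 0):
            raise CountValidationError("counts must be nonnegative")
        if np.any(vals != np.floor(vals)):
            raise CountValidationError("counts must be integers")
        frame = frame.astype(np.int64)
        bad_b = frame["opioid_beneficiaries"] > frame["total_beneficiaries"]
        bad_p = frame["opioid_claims"] > frame["total_claims"]
        if bad_b.any() or bad_p.any():
            offenders = frame.index[bad_b | bad_p].tolist()
            raise CountValidationError(
                f"opioid counts exceed totals for {offenders[:5]}"
            )
        self.df = frame

    # -- construction / IO ------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountTable":
        return cls(pd.read_csv(path, dtype={"county": str}))

    @classmethod
    def from_records(
        cls, records: Iterable[Mapping[str, object]]
    ) -> "CountTable":
        return cls(pd.DataFrame.from_records(list(records)))

    def to_csv(self, path: str | Path) -> None:
        self.df.reset_index().to_csv(path, index=False)

    # -- views ------------------------------------------------------------

    @property
    def counties(self) -> list[str]:
        return sorted(self.df.index.get_level_values("county").unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.df.index.get_level_values("year").unique())

    def arrays(
        self, counties: Sequence[str], year: int, count_kind: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """(events, baselines) for ``counties`` in ``year``, as int64 arrays."""
        base_col, event_col = _kind_columns(count_kind)
        keys = [(c, year) for c in counties]
        missing = [k for k in keys if k not in self.df.index]
        if missing:
            raise MissingCountsError(missing)
        sub = self.df.loc[keys]
        return (
            sub[event_col].to_numpy(np.int64),
            sub[base_col].to_numpy(np.int64),
        )

    def events_series(self, year: int, count_kind: str) -> pd.Series:
        _, event_col = _kind_columns(count_kind)
        return self.df.xs(year, level="year")[event_col]

    def zero_filled(self, counties: Sequence[str], years: Sequence[int]) -> "CountTable":
        """Add all-zero rows for missing (county, year) keys, with a warning.

        Public count releases suppress small cells; zero-filling is the
        stated convention for counties absent from a year's table.
        """
        full = pd.MultiIndex.from_product(
            [[str(c) for c in counties], [int(y) for y in years]],
            names=["county", "year"],
        )
        missing = full.difference(self.df.index)
        if len(missing) == 0:
            return self
        logger.warning("zero-filling %d missing (county, year) rows: %s",
                       len(missing), list(missing[:5]))
        add = pd.DataFrame(0, index=missing, columns=list(COUNT_COLUMNS))
        return CountTable(pd.concat([self.df, add]))

    def with_events(
        self, year: int, count_kind: str, counties: Sequence[str], events: np.ndarray
    ) -> "CountTable":
        """Copy of the table with the year's event column replaced (null replicates)."""
        base_col, event_col = _kind_columns(count_kind)
        df = self.df.copy()
        keys = [(c, year) for c in counties]
        df.loc[keys, event_col] = np.asarray(events, dtype=np.int64)
        return CountTable(df)


def _kind_columns(count_kind: str) -> tuple[str, str]:
    try:
        return COUNT_KINDS[count_kind]
    except KeyError:
        raise ValueError(
            f"count_kind must be one of {sorted(COUNT_KINDS)}, got {count_kind!r}"
        ) from None


def aggregate_counts(
    table: CountTable,
    cluster: Iterable[str],
    year: int,
    count_kind: str,
    roster: Sequence[str] | None = None,
) -> ClusterCounts:
    """Sum events/baselines over ``cluster``; totals run over the whole roster.

    ``roster`` defaults to every county present in the table for ``year``.
    """
    base_col, event_col = _kind_columns(count_kind)
    year_df = table.df.xs(year, level="year")
    if roster is None:
        roster = list(year_df.index)
    else:
        missing = [(c, year) for c in roster if c not in year_df.index]
        if missing:
            raise MissingCountsError(missing)
        year_df = year_df.loc[list(roster)]
    cluster = set(cluster)
    missing = [(c, year) for c in cluster if c not in year_df.index]
    if missing:
        raise MissingCountsError(missing)
    in_cluster = year_df.index.isin(cluster)
    return ClusterCounts(
        event=int(year_df.loc[in_cluster, event_col].sum()),
        baseline=int(year_df.loc[in_cluster, base_col].sum()),
        total_event=int(year_df[event_col].sum()),
        total_baseline=int(year_df[base_col].sum()),
    )
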