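"""Adaptive binning with total-k-anonymity verification.

Aggregate views of a cohort (counts of individuals matching filters) can
re-identify people when some filter combination isolates fewer than k
individuals.  Standard k-anonymity protects only declared
quasi-identifiers; here *every* attribute is treated as both
quasi-identifying and sensitive ("total" k-anonymity): no sequence of
single-value filters over distinct columns may ever yield a non-empty
group smaller than k.

Verification combines a fast greedy test (repeatedly restrict to the
globally rarest value; any encountered count < k fails) with an
exhaustive recursive brute-force check.  The greedy test is one-sided —
a greedy failure is always a true failure, but a greedy pass must be
confirmed by brute force.

Adaptive binning starts each attribute at its finest hierarchy level and,
while verification fails, coarsens the column holding the rarest value by
one level (or removes it when no coarser level exists).  Hierarchy levels
are exhaustive, non-overlapping and nested, so row counts are conserved
under coarsening and the loop terminates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MISSING_BIN = "missing"

__all__ = [
    "BinnerHierarchy",
    "builtin_hierarchies",
    "greedy_filter",
    "greedy_privacy_test",
    "brute_force_privacy_test",
    "privacy_satisfied",
    "adaptive_bin",
    "aggregate_counts",
    "BruteForceBudgetExceeded",
]


class BruteForceBudgetExceeded(RuntimeError):
    """The exhaustive check ran out of its state budget; result unknown."""


@dataclass(frozen=True)
class IntervalLevel:
    """One precision level: labelled half-open intervals [lo, hi) covering R."""

    bins: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        edges = sorted((lo, hi) for _, lo, hi in self.bins)
        lo0 = edges[0][0]
        if not math.isinf(lo0) or edges[-1][1] != math.inf:
            raise ValueError("interval level must cover (-inf, inf)")
        for (_, h1), (l2, _) in zip(edges, edges[1:]):
            if h1 != l2:
                raise ValueError("interval level must be exhaustive and disjoint")

    def label(self, value: float) -> str:
        for name, lo, hi in self.bins:
            if lo <= value < hi:
                return name
        raise AssertionError("unreachable: intervals cover the line")


@dataclass
class BinnerHierarchy:
    """Ordered coarse-graining levels (finest first) for one attribute."""

    attribute: str
    levels: list[IntervalLevel] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def bin(self, values: pd.Series, level: int) -> pd.Series:
        """Label values at the given level; missing gets its own bin."""
        lv = self.levels[level]
        vals = values.astype(float)
        out = vals.map(lambda v: MISSING_BIN if pd.isna(v) else lv.label(v))
        return out.astype(object)


def builtin_hierarchies() -> dict[str, BinnerHierarchy]:
    """Built-in birth-year and BMI hierarchies.

    Birth year: decades with adapted tails (<1940, 1940s, 1950s, 1960+),
    then a two-bin split at 1950.  BMI: the four clinical classes
    (underweight < 18.5, normal [18.5, 25), overweight [25, 30),
    obesity ≥ 30), then the two merged classes split at 25.
    """
    inf = math.inf
    birth_year = BinnerHierarchy(
        "birth_year",
        [
            IntervalLevel(
                (
                    ("less than 1940", -inf, 1940.0),
                    ("1940s", 1940.0, 1950.0),
                    ("1950s", 1950.0, 1960.0),
                    ("1960+", 1960.0, inf),
                )
            ),
            IntervalLevel(
                (("less than 1950", -inf, 1950.0), ("1950+", 1950.0, inf))
            ),
        ],
    )
    bmi = BinnerHierarchy(
        "bmi",
        [
            IntervalLevel(
                (
                    ("underweight", -inf, 18.5),
                    ("normal", 18.5, 25.0),
                    ("overweight", 25.0, 30.0),
                    ("obesity", 30.0, inf),
                )
            ),
            IntervalLevel(
                (("normal-", -inf, 25.0), ("overweight+", 25.0, inf))
            ),
        ],
    )
    return {"birth_year": birth_year, "bmi": bmi}


# ---------------------------------------------------------------------------
# verification (working tables are DataFrames of labels)


def greedy_filter(table: pd.DataFrame) -> tuple[Optional[str], Optional[str], int]:
    """The (column, value) pair with the globally smallest value frequency.

    Ties break by column declaration order, then by bin label order.
    With no columns the empty marker ``(None, None, len(table))`` returns.
    """
    best: tuple[Optional[str], Optional[str], int] = (None, None, len(table))
    for col in table.columns:
        counts = table[col].value_counts()
        if counts.empty:
            continue
        nmin = int(counts.min())
        vmin = min(str(v) for v, c in counts.items() if int(c) == nmin)
        # ties with the initial empty marker still select a real column;
        # ties between columns keep the first declared
        if nmin < best[2] or best[0] is None:
            best = (col, vmin, nmin)
    return best


def greedy_privacy_test(table: pd.DataFrame, k: int) -> bool:
    """Fast necessary check: follow the rarest value down, fail on any count < k."""
    _check_k(k)
    d = table
    while len(d.columns) > 0:
        c, v, n = greedy_filter(d)
        if c is None:
            return True
        if n < k:
            return False
        d = d.loc[d[c].astype(str) == v].drop(columns=[c])
    return True


def brute_force_privacy_test(
    table: pd.DataFrame, k: int, max_states: int = 10**6
) -> bool:
    """Exhaustive check over all nested single-value filter sequences.

    True iff every non-empty group reachable by filtering on one value
    per column (in any order, any depth) has at least k rows.  Raises
    :class:`BruteForceBudgetExceeded` when more than ``max_states``
    recursion states would be explored — never a silent pass.
    """
    _check_k(k)
    cols = list(table.columns)
    arr = {c: table[c].astype(str).to_numpy() for c in cols}
    all_rows = np.arange(len(table))
    budget = {"states": 0}
    memo: dict[tuple[frozenset, frozenset], bool] = {}

    def recurse(rows: np.ndarray, remaining: tuple[str, ...]) -> bool:
        if not remaining:
            return True
        key = (frozenset(rows.tolist()), frozenset(remaining))
        if key in memo:
            return memo[key]
        budget["states"] += 1
        if budget["states"] > max_states:
            raise BruteForceBudgetExceeded(
                f"exceeded {max_states} explored states; raise max_states to decide"
            )
        ok = True
        for ci, c in enumerate(remaining):
            col = arr[c][rows]
            values, counts = np.unique(col, return_counts=True)
            if (counts < k).any():
                ok = False
                break
            rest = remaining[:ci] + remaining[ci + 1:]
            for v in values:
                sub = rows[col == v]
                if not recurse(sub, rest):
                    ok = False
                    break
            if not ok:
                break
        memo[key] = ok
        return ok

    return recurse(all_rows, tuple(cols))


def privacy_satisfied(
    table: pd.DataFrame,
    k: int,
    max_states: int = 10**6,
    counters: Optional[dict] = None,
) -> bool:
    """Greedy test first; the exhaustive check runs only on a greedy pass."""
    _check_k(k)
    if counters is not None:
        counters.setdefault("greedy_calls", 0)
        counters.setdefault("brute_force_calls", 0)
        counters["greedy_calls"] += 1
    if not greedy_privacy_test(table, k):
        return False
    if counters is not None:
        counters["brute_force_calls"] += 1
    return brute_force_privacy_test(table, k, max_states=max_states)


def _check_k(k: int) -> None:
    if k < 2:
        raise ValueError("k must be >= 2")


# ---------------------------------------------------------------------------
# adaptive binning


def adaptive_bin(
    cohort: pd.DataFrame,
    k: int,
    hierarchies: dict[str, BinnerHierarchy],
    columns: Optional[list[str]] = None,
    max_states: int = 10**6,
) -> pd.DataFrame:
    """Coarsen/remove columns until the binned table is totally k-anonymous.

    ``columns`` selects the attributes of the view (default: all columns
    with a hierarchy plus all non-numeric columns of the cohort).
    Numeric columns must have a hierarchy; non-numeric columns enter at
    their raw labels and, having no coarser level, are removed when they
    block anonymity.  Missing values form their own bin at every level.
    """
    _check_k(k)
    if columns is None:
        columns = [
            c
            for c in cohort.columns
            if c in hierarchies or not pd.api.types.is_numeric_dtype(cohort[c])
        ]
    levels: dict[str, int] = {}
    binned = pd.DataFrame(index=cohort.index)
    for c in columns:
        if c in hierarchies:
            levels[c] = 0
            binned[c] = hierarchies[c].bin(cohort[c], 0)
        else:
            if pd.api.types.is_numeric_dtype(cohort[c]):
                raise ValueError(f"numeric column {c!r} has no binner hierarchy")
            col = cohort[c]
            binned[c] = (
                col.astype(object).where(~col.isna(), MISSING_BIN).astype(str)
            )

    while not privacy_satisfied(binned, k, max_states=max_states):
        c, _, _ = greedy_filter(binned)
        if c is None:  # no columns left; vacuously private
            break
        if c in hierarchies and levels[c] + 1 < hierarchies[c].n_levels:
            levels[c] += 1
            binned[c] = hierarchies[c].bin(cohort[c], levels[c])
        else:
            binned = binned.drop(columns=[c])
    return binned


def aggregate_counts(binned: pd.DataFrame, filters: dict[str, str]) -> int:
    """Exact count of rows matching a conjunction of column=value filters.

    On a verified table every non-zero count is at least k by
    construction.  Filtering on a removed column is an error.
    """
    mask = np.ones(len(binned), dtype=bool)
    for col, val in filters.items():
        if col not in binned.columns:
            raise KeyError(f"column {col!r} not present in the anonymized view")
        mask &= (binned[col].astype(str) == str(val)).to_numpy()
    return int(mask.sum())
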