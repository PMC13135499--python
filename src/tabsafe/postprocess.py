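"""Constraint-driven rejection sampling for generated cohorts.

Generative models capture marginal distributions well but routinely emit
clinically impossible records — a male with cervical cancer, a BMI
outside human range.  Expert-defined constraints repair this after the
fact: generated rows violating any row-level rule are discarded and the
generator is called again until the target size is reached.  Because the
rules come from domain knowledge (the config), not from the private
training records, this step does not touch the training data and leaves
any formal privacy guarantee of the generator intact.

Rule kinds:

* ``implication`` — if the antecedent predicate holds, the consequent
  must too (e.g. sex == Male ⇒ cancer ∉ {cervical}); rows where the
  antecedent cell is missing satisfy the rule vacuously;
* ``range`` — a numeric column must lie in [lo, hi];
* ``dependency`` — |corr(a, b) − target| ≤ tol, checked on the accepted
  batch as a whole (severity ``reject_batch``).

A default oncology rule pack encodes the sex-specific malignancies:
cervical, placental, endometrial and ovarian cancers occur only in
females; prostate and testicular cancers only in males.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .schema import StudyConfig

__all__ = [
    "ConstraintRule",
    "RejectionLog",
    "compile_rules",
    "default_oncology_rules",
    "accept_mask",
    "rejection_sample",
    "InfeasibleConstraints",
]

_COMPARATORS: dict[str, Callable[[pd.Series, Any], pd.Series]] = {
    "==": lambda s, v: s == v,
    "!=": lambda s, v: s != v,
    "<": lambda s, v: s.astype(float) < float(v),
    "<=": lambda s, v: s.astype(float) <= float(v),
    ">": lambda s, v: s.astype(float) > float(v),
    ">=": lambda s, v: s.astype(float) >= float(v),
    "in": lambda s, v: s.isin(list(v)),
    "not_in": lambda s, v: ~s.isin(list(v)),
}


class InfeasibleConstraints(RuntimeError):
    """Target size not reachable within the iteration budget."""

    def __init__(self, message: str, log: "RejectionLog") -> None:
        super().__init__(message)
        self.log = log


@dataclass
class ConstraintRule:
    """One executable acceptance predicate."""

    name: str
    kind: str  # implication | range | dependency
    severity: str = "reject_row"
    antecedent: Optional[tuple[str, str, Any]] = None  # (column, cmp, value)
    consequent: Optional[tuple[str, str, Any]] = None
    column: Optional[str] = None
    lo: float = -np.inf
    hi: float = np.inf
    column_a: Optional[str] = None
    column_b: Optional[str] = None
    target: float = 0.0
    tol: float = 0.0

    def row_mask(self, batch: pd.DataFrame) -> pd.Series:
        """True where the row satisfies the rule (row-level kinds only)."""
        if self.kind == "implication":
            col, cmp, val = self.antecedent
            ante = _COMPARATORS[cmp](batch[col], val)
            ante &= ~batch[col].isna()  # missing antecedent ⇒ vacuously true
            ccol, ccmp, cval = self.consequent
            cons = _COMPARATORS[ccmp](batch[ccol], cval)
            cons |= batch[ccol].isna()
            return ~ante | cons
        if self.kind == "range":
            col = batch[self.column].astype(float)
            return col.isna() | ((col >= self.lo) & (col <= self.hi))
        raise ValueError(f"rule {self.name!r} is not row-level")

    def batch_ok(self, batch: pd.DataFrame) -> bool:
        """Dependency check on the accepted batch as a whole."""
        if self.kind != "dependency":
            raise ValueError(f"rule {self.name!r} is not batch-level")
        a = batch[self.column_a].astype(float)
        b = batch[self.column_b].astype(float)
        mask = ~(a.isna() | b.isna())
        if mask.sum() < 3:
            return False
        r = float(np.corrcoef(a[mask], b[mask])[0, 1])
        return abs(r - self.target) <= self.tol


@dataclass
class RejectionLog:
    rejections: dict[str, int] = field(default_factory=dict)
    iterations: int = 0
    generated: int = 0
    accepted: int = 0

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.generated if self.generated else 1.0

    def to_dict(self) -> dict[str, Any]:
        return {
            "rejections": dict(self.rejections),
            "iterations": self.iterations,
            "generated": self.generated,
            "accepted": self.accepted,
            "acceptance_rate": self.acceptance_rate,
        }


def compile_rules(
    rule_specs: Sequence[dict[str, Any]], config: StudyConfig
) -> list[ConstraintRule]:
    """Turn declarative rule specs (e.g. from the config YAML) into
    executable :class:`ConstraintRule` objects, validating columns and
    comparators against the schema."""
    declared = set(config.column_names)
    rules: list[ConstraintRule] = []
    for i, spec in enumerate(rule_specs):
        kind = spec.get("kind")
        name = spec.get("name", f"rule_{i}")
        if kind == "implication":
            ante = (spec["if"]["column"], spec["if"].get("cmp", "=="), spec["if"]["value"])
            cons = (
                spec["then"]["column"],
                spec["then"].get("cmp", "=="),
                spec["then"]["value"],
            )
            for col, cmp, _ in (ante, cons):
                if col not in declared:
                    raise ValueError(f"rule {name!r}: undeclared column {col!r}")
                if cmp not in _COMPARATORS:
                    raise ValueError(f"rule {name!r}: unknown comparator {cmp!r}")
            rules.append(
                ConstraintRule(name=name, kind=kind, antecedent=ante, consequent=cons)
            )
        elif kind == "range":
            col = spec["column"]
            if col not in declared:
                raise ValueError(f"rule {name!r}: undeclared column {col!r}")
            rules.append(
                ConstraintRule(
                    name=name,
                    kind=kind,
                    column=col,
                    lo=float(spec.get("lo", -np.inf)),
                    hi=float(spec.get("hi", np.inf)),
                )
            )
        elif kind == "dependency":
            a, b = spec["column_a"], spec["column_b"]
            for col in (a, b):
                if col not in declared:
                    raise ValueError(f"rule {name!r}: undeclared column {col!r}")
            tol = float(spec["tol"])
            if tol <= 0:
                raise ValueError(f"rule {name!r}: tol must be > 0")
            rules.append(
                ConstraintRule(
                    name=name,
                    kind=kind,
                    severity="reject_batch",
                    column_a=a,
                    column_b=b,
                    target=float(spec["target"]),
                    tol=tol,
                )
            )
        else:
            raise ValueError(f"rule {name!r}: unknown kind {kind!r}")
    return rules


#: Sex-specific malignancies enforced by the default oncology rule pack.
FEMALE_ONLY_CANCERS = ("cervical", "placental", "endometrial", "ovarian")
MALE_ONLY_CANCERS = ("prostate", "testicular")


def default_oncology_rules(
    sex_column: str = "sex",
    cancer_column: str = "cancer",
    female_label: str = "Female",
    male_label: str = "Male",
) -> list[dict[str, Any]]:
    """Declarative spec of the sex-specific cancer constraints."""
    return [
        {
            "name": "female_only_cancers",
            "kind": "implication",
            "if": {"column": sex_column, "cmp": "==", "value": male_label},
            "then": {
                "column": cancer_column,
                "cmp": "not_in",
                "value": list(FEMALE_ONLY_CANCERS),
            },
        },
        {
            "name": "male_only_cancers",
            "kind": "implication",
            "if": {"column": sex_column, "cmp": "==", "value": female_label},
            "then": {
                "column": cancer_column,
                "cmp": "not_in",
                "value": list(MALE_ONLY_CANCERS),
            },
        },
    ]


def accept_mask(
    batch: pd.DataFrame, rules: Sequence[ConstraintRule]
) -> tuple[np.ndarray, dict[str, int]]:
    """Row acceptance mask under all row-level rules, plus per-rule
    rejection counts (a row failing several rules counts once per rule)."""
    mask = np.ones(len(batch), dtype=bool)
    counts: dict[str, int] = {}
    for rule in rules:
        if rule.severity != "reject_row":
            continue
        ok = rule.row_mask(batch).to_numpy(bool)
        counts[rule.name] = int((~ok).sum())
        mask &= ok
    return mask, counts


def rejection_sample(
    generate: Callable[[int, int], pd.DataFrame],
    rules: Sequence[ConstraintRule],
    n_target: int,
    max_iter: int = 50,
    seed: int = 0,
    min_acceptance_for_planning: float = 0.1,
) -> tuple[pd.DataFrame, RejectionLog]:
    """Generate until ``n_target`` rule-satisfying rows are collected.

    ``generate(n, seed)`` must return a batch of n conforming rows.  Each
    iteration requests the remaining deficit inflated by the inverse of
    the observed acceptance rate (floored at
    ``min_acceptance_for_planning``) so the iteration count stays
    bounded.  Batch-level dependency rules are re-checked on the final
    accepted set; raises :class:`InfeasibleConstraints` (with the partial
    log attached) when the budget runs out — never a silent undersize.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rng = np.random.default_rng(seed)
    log = RejectionLog()
    pieces: list[pd.DataFrame] = []
    collected = 0
    while collected < n_target and log.iterations < max_iter:
        deficit = n_target - collected
        rate = max(log.acceptance_rate, min_acceptance_for_planning)
        request = min(int(np.ceil(deficit / rate)), 10 * n_target)
        batch = generate(request, int(rng.integers(0, 2**31 - 1)))
        mask, counts = accept_mask(batch, rules)
        for name, c in counts.items():
            log.rejections[name] = log.rejections.get(name, 0) + c
        log.iterations += 1
        log.generated += len(batch)
        log.accepted += int(mask.sum())
        kept = batch.loc[mask]
        pieces.append(kept)
        collected += len(kept)
    if collected < n_target:
        raise InfeasibleConstraints(
            f"only {collected}/{n_target} acceptable rows after "
            f"{log.iterations} iterations "
            f"(acceptance rate {log.acceptance_rate:.3g})",
            log,
        )
    out = pd.concat(pieces, ignore_index=True).iloc[:n_target].reset_index(drop=True)
    for rule in rules:
        if rule.severity == "reject_batch" and not rule.batch_ok(out):
            raise InfeasibleConstraints(
                f"batch-level rule {rule.name!r} not satisfied by the final set",
                log,
            )
    return out, log
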