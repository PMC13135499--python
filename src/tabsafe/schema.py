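"""Study configuration, cohort table I/O and schema validation.

A cohort is held in memory as a :class:`pandas.DataFrame` whose columns
follow a declared schema: continuous columns are float64, date columns are
``datetime64[ns]``, binary/categorical columns are objects drawn from a
declared category list, and missing cells are NaN/NaT regardless of role.
On disk a cohort is a delimited text table (comma by default, tab accepted)
with a single configurable missing-value token, and the configuration is a
YAML document naming each column's role, sensitivity, binner hierarchy and
the study-wide privacy constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

ROLES = ("continuous", "date", "binary", "categorical", "identifier")

#: Default minimum group size for any disclosed aggregate: aggregate views
#: must never reveal groups of fewer than this many individuals.
DEFAULT_K_ANONYMITY = 10
DEFAULT_SEED = 2026


class ConfigError(ValueError):
    """Raised for malformed or inconsistent study configurations."""


class TableError(ValueError):
    """Raised when a table on disk cannot be coerced to its declared schema."""


@dataclass(frozen=True)
class ColumnSpec:
    """Declared role and metadata of a single cohort column."""

    name: str
    role: str
    units: str = ""
    categories: tuple[str, ...] = ()
    sensitive: bool = False
    binner: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"column {self.name!r}: unknown role {self.role!r}")
        if self.role in ("binary", "categorical"):
            if not self.categories:
                raise ConfigError(
                    f"column {self.name!r}: role {self.role!r} requires categories"
                )
            if self.role == "binary" and len(self.categories) != 2:
                raise ConfigError(
                    f"column {self.name!r}: binary requires exactly 2 categories, "
                    f"got {len(self.categories)}"
                )
            if len(set(self.categories)) != len(self.categories):
                raise ConfigError(f"column {self.name!r}: duplicate categories")
        elif self.categories:
            raise ConfigError(
                f"column {self.name!r}: categories only allowed for binary/categorical"
            )


@dataclass
class LossWeights:
    """Weights of the auxiliary generative losses.

    alpha scales the correlation-matching term, beta the moment-matching
    term, H is the number of moment orders and epsilon a small positive
    stabiliser in the moment ratio.
    """

    alpha: float = 1.0
    beta: float = 1.0
    H: int = 3
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("loss weights must be non-negative")
        if int(self.H) != self.H or self.H < 1:
            raise ConfigError("H must be an integer >= 1")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        self.H = int(self.H)


@dataclass
class MatchConfig:
    """A pseudo-identifier set with per-variable matching spans.

    ``spans[v]`` is the absolute tolerance for numeric/date variable ``v``
    (in days for dates); categorical variables use span 0, i.e. exact match.
    """

    label: str
    spans: dict[str, float]

    def __post_init__(self) -> None:
        for v, s in self.spans.items():
            if s < 0:
                raise ConfigError(f"match config {self.label!r}: span for {v!r} < 0")

    @property
    def variables(self) -> list[str]:
        return list(self.spans)


@dataclass
class StudyConfig:
    """Full declarative description of a study table and its privacy rules."""

    columns: list[ColumnSpec]
    reference_date: date = date(2000, 1, 1)
    k_anonymity: int = DEFAULT_K_ANONYMITY
    missing_marker: str = "n.a."
    loss_weights: LossWeights = field(default_factory=LossWeights)
    constraint_rules: list[dict[str, Any]] = field(default_factory=list)
    match_configs: list[MatchConfig] = field(default_factory=list)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate column name(s): {sorted(dupes)}")
        if self.k_anonymity < 2:
            raise ConfigError("k_anonymity must be >= 2")
        declared = set(names)
        for rule in self.constraint_rules:
            for col in _rule_columns(rule):
                if col not in declared:
                    raise ConfigError(
                        f"constraint rule references undeclared column {col!r}"
                    )
        for mc in self.match_configs:
            for v in mc.variables:
                if v not in declared:
                    raise ConfigError(
                        f"match config {mc.label!r} references undeclared column {v!r}"
                    )

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def by_role(self, *roles: str) -> list[ColumnSpec]:
        return [c for c in self.columns if c.role in roles]


def _rule_columns(rule: dict[str, Any]) -> list[str]:
    cols: list[str] = []
    kind = rule.get("kind")
    if kind == "implication":
        cols.append(rule["if"]["column"])
        cols.append(rule["then"]["column"])
    elif kind == "range":
        cols.append(rule["column"])
    elif kind == "dependency":
        cols.extend([rule["column_a"], rule["column_b"]])
    return cols


# ---------------------------------------------------------------------------
# configuration I/O


def _parse_column(entry: dict[str, Any]) -> ColumnSpec:
    try:
        name = entry["name"]
        role = entry["role"]
    except KeyError as exc:
        raise ConfigError(f"column entry missing key {exc}") from exc
    return ColumnSpec(
        name=name,
        role=role,
        units=entry.get("units", ""),
        categories=tuple(str(c) for c in entry.get("categories", ())),
        sensitive=bool(entry.get("sensitive", False)),
        binner=entry.get("binner"),
    )


def config_from_dict(doc: dict[str, Any]) -> StudyConfig:
    """Build a validated :class:`StudyConfig` from a parsed YAML tree."""
    if "columns" not in doc:
        raise ConfigError("configuration must declare 'columns'")
    columns = [_parse_column(e) for e in doc["columns"]]
    ref = doc.get("reference_date", "2000-01-01")
    if isinstance(ref, str):
        ref = date.fromisoformat(ref)
    lw = doc.get("loss_weights", {})
    mcs = [
        MatchConfig(label=str(m.get("label", i + 1)), spans=dict(m["spans"]))
        for i, m in enumerate(doc.get("match_configs", []))
    ]
    return StudyConfig(
        columns=columns,
        reference_date=ref,
        k_anonymity=int(doc.get("k_anonymity", DEFAULT_K_ANONYMITY)),
        missing_marker=str(doc.get("missing_marker", "n.a.")),
        loss_weights=LossWeights(**lw) if isinstance(lw, dict) else lw,
        constraint_rules=list(doc.get("constraint_rules", [])),
        match_configs=mcs,
        seed=int(doc.get("seed", DEFAULT_SEED)),
    )


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a study configuration from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return config_from_dict(doc)


def config_to_dict(config: StudyConfig) -> dict[str, Any]:
    return {
        "columns": [
            {
                "name": c.name,
                "role": c.role,
                **({"units": c.units} if c.units else {}),
                **({"categories": list(c.categories)} if c.categories else {}),
                **({"sensitive": True} if c.sensitive else {}),
                **({"binner": c.binner} if c.binner else {}),
            }
            for c in config.columns
        ],
        "reference_date": config.reference_date.isoformat(),
        "k_anonymity": config.k_anonymity,
        "missing_marker": config.missing_marker,
        "seed": config.seed,
        "constraint_rules": config.constraint_rules,
        "match_configs": [
            {"label": m.label, "spans": m.spans} for m in config.match_configs
        ],
    }


def save_config(config: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# table I/O


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_table(path: str | Path, config: StudyConfig, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited text table and coerce it to the declared schema.

    Cells equal to the configured missing marker become NaN/NaT; any other
    unparseable cell raises :class:`TableError` naming the row and column.
    """
    sep = sep or _sep_for(path)
    raw = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    if list(raw.columns) != config.column_names:
        raise TableError(
            f"header mismatch: file has {list(raw.columns)}, "
            f"config declares {config.column_names}"
        )
    return coerce_table(raw, config)


def coerce_table(raw: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Coerce a table of strings to typed columns per the config."""
    out = pd.DataFrame(index=raw.index)
    marker = config.missing_marker
    for spec in config.columns:
        col = raw[spec.name].astype(str).str.strip()
        missing = (col == marker) | (col == "")
        if spec.role == "continuous":
            vals = pd.to_numeric(col.where(~missing), errors="coerce")
            bad = vals.isna() & ~missing
            if bad.any():
                r = int(bad.idxmax())
                raise TableError(
                    f"column {spec.name!r}, row {r}: cannot parse {col[r]!r} as number"
                )
            out[spec.name] = vals.astype(float)
        elif spec.role == "date":
            vals = pd.to_datetime(
                col.where(~missing), format="%Y-%m-%d", errors="coerce"
            )
            bad = vals.isna() & ~missing
            if bad.any():
                r = int(bad.idxmax())
                raise TableError(
                    f"column {spec.name!r}, row {r}: cannot parse {col[r]!r} "
                    "as ISO date (YYYY-MM-DD)"
                )
            out[spec.name] = vals
        elif spec.role in ("binary", "categorical"):
            known = set(spec.categories)
            bad = ~col.isin(known) & ~missing
            if bad.any():
                r = int(bad.idxmax())
                raise TableError(
                    f"column {spec.name!r}, row {r}: value {col[r]!r} not in "
                    f"declared categories {list(spec.categories)}"
                )
            out[spec.name] = col.where(~missing, np.nan).astype(object)
        else:  # identifier
            out[spec.name] = col.where(~missing, np.nan).astype(object)
    return out


def write_table(
    cohort: pd.DataFrame, path: str | Path, config: StudyConfig, sep: str | None = None
) -> None:
    """Write a typed cohort back to delimited text with the missing marker."""
    sep = sep or _sep_for(path)
    out = format_table(cohort, config)
    out.to_csv(path, sep=sep, index=False)


def format_table(cohort: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Render a typed cohort to strings, restoring the missing marker."""
    out = pd.DataFrame(index=cohort.index)
    for spec in config.columns:
        col = cohort[spec.name]
        if spec.role == "date":
            s = col.dt.strftime("%Y-%m-%d")
        elif spec.role == "continuous":
            # integers print without a trailing .0 so round-trips stay textual
            s = col.map(
                lambda v: ""
                if pd.isna(v)
                else (str(int(v)) if float(v).is_integer() else repr(float(v)))
            )
        else:
            s = col.astype(object)
        out[spec.name] = s.where(~col.isna(), config.missing_marker)
        out[spec.name] = out[spec.name].fillna(config.missing_marker)
    return out


# ---------------------------------------------------------------------------
# validation


def validate_table(cohort: pd.DataFrame, config: StudyConfig) -> dict[str, Any]:
    """Check a cohort against its schema; violations are reported, not raised.

    Returns a JSON-serialisable report with per-column category/type
    violations, a structure check on the column set, and the structure
    score (1.0 when the column sets and order agree).
    """
    declared = config.column_names
    present = list(cohort.columns)
    missing_cols = [c for c in declared if c not in present]
    extra_cols = [c for c in present if c not in declared]
    structure_ok = not missing_cols and not extra_cols and present == declared
    violations: list[dict[str, Any]] = []
    for spec in config.columns:
        if spec.name not in cohort.columns:
            continue
        col = cohort[spec.name]
        if spec.role in ("binary", "categorical"):
            bad = ~col.isna() & ~col.isin(spec.categories)
            for idx in cohort.index[bad]:
                violations.append(
                    {"column": spec.name, "row": int(idx), "value": str(col[idx]),
                     "kind": "category"}
                )
        elif spec.role == "continuous":
            if not pd.api.types.is_numeric_dtype(col):
                violations.append({"column": spec.name, "kind": "dtype"})
    return {
        "n_rows": int(len(cohort)),
        "structure": {
            "ok": bool(structure_ok),
            "missing_columns": missing_cols,
            "extra_columns": extra_cols,
            "score": 1.0 if structure_ok else 0.0,
        },
        "violations": violations,
        "n_violations": len(violations),
    }


def save_report(report: dict[str, Any], path: str | Path) -> None:
    """Serialise a report as JSON with stable key ordering."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (date, pd.Timestamp)):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
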