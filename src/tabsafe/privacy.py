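"""Empirical disclosure-risk metrics for synthetic cohorts.

Each metric simulates an attack scenario against a released synthetic
table and returns a scalar with an explicit orientation (higher-is-safer
or lower-is-safer):

* cluster-based anonymity scores (k-anonymity, l-diversity, k-map,
  Δ-presence) built on seeded K-Means at several granularities with
  fallback logic for unreliable (under-occupied) clusterings;
* nearest-neighbour re-identification scores (identifiability and
  single-out: the fraction of real records closer to a synthetic record
  than to their second-nearest real neighbour);
* a density-based membership-inference attack (k-NN density of synthetic
  points around train vs holdout records, summarised as accuracy and AUC);
* correct-attribution probability (CAP) in zero and generalized modes,
  and the CAP-based inference risk for a declared known/secret split;
* a linkability score (two disjoint feature subsets pointing to the same
  synthetic record that itself points back to the same real individual);
* the match-rate heuristic (synthetic rows approximately matching a real
  row on a pseudo-identifier set within per-variable spans), with a
  real-to-real baseline excluding self-matches.

Distances are Euclidean on standardized features, with standardization
fitted on the real table only.
"""

from __future__ import annotations

from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances

from .schema import MatchConfig

DEFAULT_GRANULARITIES = (2, 5, 10, 15)
MIN_CLUSTER_OCCUPANCY = 5

__all__ = [
    "cluster_k_anonymity",
    "l_diversity",
    "k_map",
    "delta_presence",
    "identifiability_score",
    "single_out_score",
    "mia_density",
    "cap_score",
    "inference_risk",
    "linkability_score",
    "match_rate",
    "baseline_match_rate",
    "privacy_report",
]


# ---------------------------------------------------------------------------
# feature-space helpers


def _standardize(real: np.ndarray, *others: np.ndarray) -> list[np.ndarray]:
    mu = real.mean(axis=0)
    sd = real.std(axis=0)
    sd[sd == 0] = 1.0
    return [(x - mu) / sd for x in (real, *others)]


def _numeric_keys(
    real: pd.DataFrame, synth: pd.DataFrame, columns: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Numeric representation of key columns: standardized numerics/dates,
    one-hot categoricals (category vocabulary pooled over both tables)."""
    blocks_r, blocks_s = [], []
    for c in columns:
        rc, sc = real[c], synth[c]
        if pd.api.types.is_datetime64_any_dtype(rc):
            rv = (rc - pd.Timestamp("2000-01-01")).dt.days.to_numpy(float)
            sv = (sc - pd.Timestamp("2000-01-01")).dt.days.to_numpy(float)
        elif pd.api.types.is_numeric_dtype(rc):
            rv = rc.to_numpy(float)
            sv = sc.to_numpy(float)
        else:
            cats = sorted(
                set(rc.dropna().astype(str)) | set(sc.dropna().astype(str))
            )
            for cat in cats:
                blocks_r.append((rc.astype(str) == cat).to_numpy(float))
                blocks_s.append((sc.astype(str) == cat).to_numpy(float))
            continue
        med = np.nanmedian(rv)
        rv = np.where(np.isnan(rv), med, rv)
        sv = np.where(np.isnan(sv), med, sv)
        blocks_r.append(rv)
        blocks_s.append(sv)
    R = np.column_stack(blocks_r)
    S = np.column_stack(blocks_s) if len(synth) else np.empty((0, R.shape[1]))
    R, S = _standardize(R, S)
    return R, S


def _sensitive_tuples(table: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    out = np.empty(len(table), dtype=object)
    for i, row in enumerate(table[list(cols)].to_numpy()):
        out[i] = tuple(str(v) for v in row)
    return out


# ---------------------------------------------------------------------------
# cluster-based metrics


def _fit_clusterings(
    X: np.ndarray, granularities: Sequence[int], seed: int
) -> dict[int, KMeans]:
    if len(X) < min(granularities):
        raise ValueError(
            f"need at least {min(granularities)} rows; got {len(X)}"
        )
    out = {}
    for g in granularities:
        if g > len(X):
            continue
        out[g] = KMeans(n_clusters=g, n_init=10, random_state=seed).fit(X)
    return out


def _occupancies(labels: np.ndarray, g: int) -> np.ndarray:
    return np.bincount(labels, minlength=g)


def cluster_k_anonymity(
    table: pd.DataFrame,
    key_features: Sequence[str],
    granularities: Sequence[int] = DEFAULT_GRANULARITIES,
    seed: int = 0,
    details: Optional[dict] = None,
) -> int:
    """Minimum K-Means cluster occupancy over reliable granularities.

    A granularity is unreliable when any cluster is empty or holds fewer
    than :data:`MIN_CLUSTER_OCCUPANCY` members; unreliable granularities
    are skipped with a fallback note.  If every granularity is
    unreliable the minimum non-empty occupancy is reported instead,
    flagged in ``details``.  Higher is safer.
    """
    X, _ = _numeric_keys(table, table.iloc[:0], key_features)
    fits = _fit_clusterings(X, granularities, seed)
    reliable, fallback_scores, notes = [], [], []
    for g, km in fits.items():
        occ = _occupancies(km.labels_, g)
        nonempty = occ[occ > 0]
        if (occ == 0).any() or nonempty.min() < MIN_CLUSTER_OCCUPANCY:
            notes.append(f"granularity {g}: unreliable clustering, skipped")
            fallback_scores.append(int(nonempty.min()))
        else:
            reliable.append(int(occ.min()))
    if reliable:
        score = min(reliable)
    else:
        score = min(fallback_scores)
        notes.append("all granularities unreliable; min non-empty occupancy used")
    if details is not None:
        details["fallbacks"] = notes
        details["granularities_used"] = [
            g for g in fits if f"granularity {g}: unreliable clustering, skipped"
            not in notes
        ]
    return score


def l_diversity(
    table: pd.DataFrame,
    key_features: Sequence[str],
    sensitive_columns: Sequence[str],
    granularities: Sequence[int] = DEFAULT_GRANULARITIES,
    seed: int = 0,
    details: Optional[dict] = None,
) -> int:
    """Minimum count of distinct sensitive combinations within any cluster."""
    if not sensitive_columns:
        raise ValueError("need at least one sensitive column")
    X, _ = _numeric_keys(table, table.iloc[:0], key_features)
    fits = _fit_clusterings(X, granularities, seed)
    sens = _sensitive_tuples(table, sensitive_columns)
    scores, notes = [], []
    for g, km in fits.items():
        occ = _occupancies(km.labels_, g)
        if (occ == 0).any() or occ[occ > 0].min() < MIN_CLUSTER_OCCUPANCY:
            notes.append(f"granularity {g}: unreliable clustering, skipped")
            continue
        for c in range(g):
            members = sens[km.labels_ == c]
            scores.append(len(set(members.tolist())))
    if not scores:  # fall back to non-empty clusters only
        notes.append("all granularities unreliable; non-empty clusters used")
        for g, km in fits.items():
            for c in np.unique(km.labels_):
                members = sens[km.labels_ == c]
                scores.append(len(set(members.tolist())))
    if details is not None:
        details["fallbacks"] = notes
    return int(min(scores))


def k_map(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    key_features: Sequence[str],
    granularities: Sequence[int] = DEFAULT_GRANULARITIES,
    seed: int = 0,
) -> int:
    """Smallest synthetic occupancy across clusters fitted on the real data."""
    if len(synth) == 0:
        raise ValueError("synthetic table is empty")
    R, S = _numeric_keys(real, synth, key_features)
    fits = _fit_clusterings(R, granularities, seed)
    score = None
    for g, km in fits.items():
        labels = km.predict(S)
        occ = np.bincount(labels, minlength=g)
        cand = int(occ.min())
        score = cand if score is None else min(score, cand)
    return int(score)


def delta_presence(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    key_features: Sequence[str],
    sensitive_columns: Sequence[str],
    granularities: Sequence[int] = DEFAULT_GRANULARITIES,
    seed: int = 0,
) -> float:
    """Maximum per-cluster fraction of real sensitive combinations that also
    appear in the corresponding synthetic cluster.  Lower is safer."""
    if len(synth) == 0:
        raise ValueError("synthetic table is empty")
    R, S = _numeric_keys(real, synth, key_features)
    fits = _fit_clusterings(R, granularities, seed)
    sens_r = _sensitive_tuples(real, sensitive_columns)
    sens_s = _sensitive_tuples(synth, sensitive_columns)
    worst = 0.0
    for g, km in fits.items():
        labels_s = km.predict(S)
        for c in range(g):
            rset = set(sens_r[km.labels_ == c].tolist())
            if not rset:
                continue
            sset = set(sens_s[labels_s == c].tolist())
            worst = max(worst, len(rset & sset) / len(rset))
    return float(worst)


# ---------------------------------------------------------------------------
# nearest-neighbour re-identification


def _second_nearest_real(Xr: np.ndarray) -> np.ndarray:
    """Distance of each real record to its second-nearest *other* real record."""
    n = len(Xr)
    if n < 2:
        raise ValueError("need at least 2 real records")
    d = pairwise_distances(Xr)
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    return d[:, min(1, n - 2)]


def identifiability_score(real: np.ndarray, synth: np.ndarray) -> float:
    """Fraction of real records strictly closer to some synthetic record than
    to their second-nearest real neighbour.  Lower is safer; ties count as
    not-closer."""
    Xr = np.asarray(real, float)
    Xs = np.asarray(synth, float)
    Xr, Xs = _standardize(Xr, Xs)
    if len(Xs) == 0:
        return 0.0
    d_syn = pairwise_distances(Xr, Xs).min(axis=1)
    d_real2 = _second_nearest_real(Xr)
    return float(np.mean(d_syn < d_real2))


def single_out_score(real: np.ndarray, synth: np.ndarray) -> float:
    """Probability of singling out a real individual from the synthetic data.

    Same second-neighbour construction as :func:`identifiability_score`,
    reported separately because the two risks are tracked as distinct
    metrics in reports.
    """
    return identifiability_score(real, synth)


def mia_density(
    train_real: np.ndarray,
    holdout_real: np.ndarray,
    synth: np.ndarray,
    neighbors: Optional[int] = None,
) -> tuple[float, float]:
    """Density-based membership inference: (attack accuracy, attack AUC).

    The membership score of a real record is the local density of
    synthetic points around it (inverse mean distance to its k nearest
    synthetic neighbours).  AUC is the rank probability that a training
    record outscores a holdout record; accuracy thresholds at the median
    score (balanced prior).  0.5 for both ≈ no membership leakage.
    """
    Xt = np.asarray(train_real, float)
    Xh = np.asarray(holdout_real, float)
    Xs = np.asarray(synth, float)
    if len(Xs) == 0:
        raise ValueError("synthetic table is empty")
    k = neighbors if neighbors is not None else int(np.ceil(np.sqrt(len(Xs))))
    if k >= len(Xs):
        raise ValueError(f"neighbors={k} must be < n_synth={len(Xs)}")
    Xt, Xh, Xs = _standardize(Xt, Xh, Xs)

    def score(X: np.ndarray) -> np.ndarray:
        d = pairwise_distances(X, Xs)
        d.sort(axis=1)
        return -d[:, :k].mean(axis=1)  # higher = denser = more member-like

    st, sh = score(Xt), score(Xh)
    # rank-based AUC with tie handling
    all_scores = np.concatenate([st, sh])
    ranks = stats.rankdata(all_scores)
    auc = (ranks[: len(st)].sum() - len(st) * (len(st) + 1) / 2) / (
        len(st) * len(sh)
    )
    thr = np.median(all_scores)
    acc = 0.5 * (np.mean(st > thr) + np.mean(sh <= thr))
    return float(acc), float(auc)


# ---------------------------------------------------------------------------
# attribution / inference / linkability


def _mode(values: Sequence[str]) -> str:
    """Modal value with deterministic lexical tie-break."""
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def cap_score(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    key_columns: Sequence[str],
    sensitive_column: str,
    mode: str = "zero",
) -> float:
    """Correct attribution probability: attacker success in guessing the
    sensitive value from key attributes via the synthetic table.

    Zero mode requires exact key matches (no match contributes 0);
    generalized mode uses the nearest synthetic records in key space.
    The attacker guesses the modal sensitive value of the matched set;
    lower success is safer (protection = 1 − success).
    """
    if sensitive_column not in synth.columns:
        raise ValueError(f"sensitive column {sensitive_column!r} absent from synth")
    truth = real[sensitive_column].astype(str).to_numpy()
    if mode == "zero":
        key = lambda df: list(
            zip(*(df[c].astype(str) for c in key_columns))
        )  # noqa: E731
        groups: dict[tuple, list[str]] = {}
        for kt, sv in zip(key(synth), synth[sensitive_column].astype(str)):
            groups.setdefault(kt, []).append(sv)
        hits = [
            1.0 if kt in groups and _mode(groups[kt]) == t else 0.0
            for kt, t in zip(key(real), truth)
        ]
        return float(np.mean(hits))
    if mode != "generalized":
        raise ValueError(f"unknown CAP mode {mode!r}")
    R, S = _numeric_keys(real, synth, key_columns)
    d = pairwise_distances(R, S)
    sens_s = synth[sensitive_column].astype(str).to_numpy()
    hits = []
    for i in range(len(R)):
        dmin = d[i].min()
        nearest = sens_s[np.isclose(d[i], dmin)]
        hits.append(1.0 if _mode(nearest.tolist()) == truth[i] else 0.0)
    return float(np.mean(hits))


def inference_risk(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    known_columns: Sequence[str],
    secret_column: str,
) -> float:
    """Probability of inferring the secret attribute from partial knowledge.

    Generalized-CAP success for the declared known/secret split; with no
    known columns the attacker's best constant guess (the synthetic modal
    class) is scored.
    """
    if not known_columns:
        guess = _mode(synth[secret_column].astype(str).tolist())
        return float(np.mean(real[secret_column].astype(str) == guess))
    return cap_score(real, synth, known_columns, secret_column, mode="generalized")


def linkability_score(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    feature_split: tuple[Sequence[str], Sequence[str]],
) -> float:
    """Fraction of real individuals linkable through two disjoint feature views.

    A real record is linked when its nearest synthetic record on subset A
    and on subset B is one and the same synthetic record, and that record's
    nearest real neighbour (on A ∪ B) is the original individual.
    Lower is safer.
    """
    A, B = (list(feature_split[0]), list(feature_split[1]))
    if set(A) & set(B):
        raise ValueError("feature subsets must be disjoint")
    if len(real) < 2:
        raise ValueError("need at least 2 real records to contrast individuals")
    if len(synth) == 0:
        return 0.0
    Ra, Sa = _numeric_keys(real, synth, A)
    Rb, Sb = _numeric_keys(real, synth, B)
    Rab, Sab = _numeric_keys(real, synth, A + B)
    na = pairwise_distances(Ra, Sa).argmin(axis=1)
    nb = pairwise_distances(Rb, Sb).argmin(axis=1)
    back = pairwise_distances(Sab, Rab).argmin(axis=1)
    linked = (na == nb) & (back[na] == np.arange(len(real)))
    return float(np.mean(linked))


# ---------------------------------------------------------------------------
# match-rate heuristic


def _match_matrix(
    query: pd.DataFrame, reference: pd.DataFrame, config: MatchConfig
) -> np.ndarray:
    """Boolean (n_query, n_reference): rows matching within span on ALL variables.

    Missing cells never match.
    """
    ok = np.ones((len(query), len(reference)), dtype=bool)
    for var, span in config.spans.items():
        q, r = query[var], reference[var]
        if pd.api.types.is_datetime64_any_dtype(q):
            qv = (q - pd.Timestamp("2000-01-01")).dt.days.to_numpy(float)
            rv = (r - pd.Timestamp("2000-01-01")).dt.days.to_numpy(float)
            ok &= np.abs(qv[:, None] - rv[None, :]) <= span
        elif pd.api.types.is_numeric_dtype(q):
            qv, rv = q.to_numpy(float), r.to_numpy(float)
            ok &= np.abs(qv[:, None] - rv[None, :]) <= span
        else:
            qv = q.astype(object).to_numpy()
            rv = r.astype(object).to_numpy()
            both = (qv[:, None] == rv[None, :])
            both &= ~pd.isna(qv)[:, None] & ~pd.isna(rv)[None, :]
            ok &= both
            continue
        ok &= ~np.isnan(qv)[:, None] & ~np.isnan(rv)[None, :]
    return ok


def match_rate(real: pd.DataFrame, synth: pd.DataFrame, config: MatchConfig) -> float:
    """Proportion of synthetic rows approximately matching ≥ 1 real row
    on every variable of the pseudo-identifier set.  Lower is safer."""
    for v in config.variables:
        if v not in real.columns or v not in synth.columns:
            raise ValueError(f"match variable {v!r} missing from a table")
    if len(synth) == 0:
        return 0.0
    return float(_match_matrix(synth, real, config).any(axis=1).mean())


def baseline_match_rate(
    real: pd.DataFrame, config: MatchConfig, id_column: str
) -> float:
    """Real-to-real coincidental match rate, excluding same-individual pairs."""
    if id_column not in real.columns:
        raise ValueError(f"id column {id_column!r} missing from real table")
    ok = _match_matrix(real, real, config)
    ids = real[id_column].astype(str).to_numpy()
    same = ids[:, None] == ids[None, :]
    ok &= ~same
    return float(ok.any(axis=1).mean())


# ---------------------------------------------------------------------------
# report assembly


def privacy_report(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    real_encoded: np.ndarray,
    synth_encoded: np.ndarray,
    key_features: Sequence[str],
    sensitive_columns: Sequence[str],
    match_configs: Sequence[MatchConfig] = (),
    id_column: Optional[str] = None,
    granularities: Sequence[int] = DEFAULT_GRANULARITIES,
    seed: int = 0,
) -> dict[str, Any]:
    """Assemble the full disclosure-risk report with orientations."""
    det_k: dict = {}
    report: dict[str, Any] = {"settings": {
        "granularities": list(granularities),
        "key_features": list(key_features),
        "sensitive_columns": list(sensitive_columns),
        "seed": seed,
    }}
    metrics: dict[str, Any] = {}
    metrics["k_anonymity_synth"] = {
        "value": cluster_k_anonymity(synth, key_features, granularities, seed, det_k),
        "orientation": "higher_is_safer",
    }
    metrics["l_diversity_synth"] = {
        "value": l_diversity(synth, key_features, sensitive_columns, granularities, seed),
        "orientation": "higher_is_safer",
    }
    metrics["k_map"] = {
        "value": k_map(real, synth, key_features, granularities, seed),
        "orientation": "higher_is_safer",
    }
    metrics["delta_presence"] = {
        "value": delta_presence(
            real, synth, key_features, sensitive_columns, granularities, seed
        ),
        "orientation": "lower_is_safer",
    }
    metrics["identifiability"] = {
        "value": identifiability_score(real_encoded, synth_encoded),
        "orientation": "lower_is_safer",
    }
    metrics["single_out"] = {
        "value": single_out_score(real_encoded, synth_encoded),
        "orientation": "lower_is_safer",
    }
    if sensitive_columns:
        metrics["cap_zero"] = {
            "value": cap_score(real, synth, key_features, sensitive_columns[0], "zero"),
            "orientation": "lower_is_safer",
        }
        metrics["cap_generalized"] = {
            "value": cap_score(
                real, synth, key_features, sensitive_columns[0], "generalized"
            ),
            "orientation": "lower_is_safer",
        }
        metrics["inference_risk"] = {
            "value": inference_risk(real, synth, key_features, sensitive_columns[0]),
            "orientation": "lower_is_safer",
        }
    for mc in match_configs:
        metrics[f"match_rate_{mc.label}"] = {
            "value": match_rate(real, synth, mc),
            "orientation": "lower_is_safer",
        }
        if id_column is not None:
            metrics[f"baseline_match_rate_{mc.label}"] = {
                "value": baseline_match_rate(real, mc, id_column),
                "orientation": "baseline",
            }
    report["metrics"] = metrics
    report["fallbacks"] = det_k.get("fallbacks", [])
    return report
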