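"""Statistical-similarity scoring, ML utility, and model ranking.

Similarity is scored per column — 1 − Kolmogorov–Smirnov statistic for
numeric and date columns, 1 − total variation distance for
binary/categorical (missing treated as its own category) — and per
column pair as 1 − |g − g̃|/2 on encoded Pearson correlations.  The
quality score is the mean of the column-shapes and pair-trends
aggregates; the diagnostic score the mean of validity (values within
declared ranges/categories) and structure (same columns and shapes).

ML utility uses the train-synthetic-test-real (TSTR) protocol with
class-weighted classifiers (logistic regression, linear SVM, gradient
boosted trees) and imbalance-aware summaries: weighted precision,
recall, F1 and the G-mean (geometric mean of per-class recalls).  An
augmentation protocol reports the delta from adding synthetic rows to a
real training set.

Competing generators are ranked per dataset with average ranks (ties
averaged), compared by the Friedman test, and separated post hoc by the
Nemenyi critical difference CD = q_α · √(k(k+1)/(6N)); a failed
(model, dataset) cell is assigned a sentinel worst rank before
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support, recall_score
from sklearn.svm import LinearSVC

from .corrdst import pairwise_correlations
from .schema import StudyConfig, validate_table

__all__ = [
    "column_shape_score",
    "pair_trend_score",
    "similarity_report",
    "tstr_evaluate",
    "augmentation_evaluate",
    "friedman_test",
    "nemenyi_rank",
    "aggregate_rankings",
    "RankTable",
]


# ---------------------------------------------------------------------------
# statistical similarity


def column_shape_score(
    real_column: pd.Series, synth_column: pd.Series, role: str
) -> float:
    """Per-column similarity in [0, 1]: 1 − KS for numeric/date, 1 − TVD for
    categorical/binary (missing is a category of its own)."""
    if role in ("continuous", "date"):
        r = real_column.dropna()
        s = synth_column.dropna()
        if len(r) == 0 or len(s) == 0:
            raise ValueError("empty column after dropping missing values")
        if role == "date":
            r = (pd.to_datetime(r) - pd.Timestamp("2000-01-01")).dt.days
            s = (pd.to_datetime(s) - pd.Timestamp("2000-01-01")).dt.days
        ks = stats.ks_2samp(r.to_numpy(float), s.to_numpy(float)).statistic
        return float(1.0 - ks)
    if role in ("binary", "categorical"):
        r = real_column.astype(object).where(~real_column.isna(), "missing")
        s = synth_column.astype(object).where(~synth_column.isna(), "missing")
        cats = sorted(set(r.astype(str)) | set(s.astype(str)))
        pr = r.astype(str).value_counts(normalize=True).reindex(cats, fill_value=0)
        ps = s.astype(str).value_counts(normalize=True).reindex(cats, fill_value=0)
        tvd = 0.5 * float(np.abs(pr - ps).sum())
        return float(1.0 - tvd)
    raise ValueError(f"unsupported role {role!r}")


def pair_trend_score(
    real_encoded: np.ndarray, synth_encoded: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean over pairs of 1 − |g − g̃|/2, plus the signed difference matrix
    (g − g̃) used for correlation heatmaps."""
    g = pairwise_correlations(real_encoded)
    gt = pairwise_correlations(synth_encoded)
    if g.shape != gt.shape:
        raise ValueError("encoded matrices have different column counts")
    m = g.shape[0]
    if m < 2:
        raise ValueError("need at least 2 columns for pair trends")
    diff = g - gt
    iu = np.triu_indices(m, k=1)
    score = float(np.mean(1.0 - np.abs(diff[iu]) / 2.0))
    return score, diff


def similarity_report(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    config: StudyConfig,
    real_encoded: Optional[np.ndarray] = None,
    synth_encoded: Optional[np.ndarray] = None,
) -> dict[str, Any]:
    """Full similarity/diagnostic report.

    quality = mean(column-shapes, pair-trends); diagnostic = mean(validity,
    structure).  Validity is the fraction of cells within declared
    categories (plus numeric dtype checks); structure requires identical
    column names and order.
    """
    shapes: dict[str, float] = {}
    for spec in config.columns:
        if spec.role == "identifier":
            continue
        shapes[spec.name] = column_shape_score(
            real[spec.name], synth[spec.name], spec.role
        )
    column_shapes = float(np.mean(list(shapes.values())))
    if real_encoded is not None and synth_encoded is not None:
        pair_trends, _ = pair_trend_score(real_encoded, synth_encoded)
    else:
        num_cols = [c.name for c in config.by_role("continuous")]
        pair_trends, _ = pair_trend_score(
            real[num_cols].dropna().to_numpy(float),
            synth[num_cols].dropna().to_numpy(float),
        )
    validation = validate_table(synth, config)
    n_cells = max(len(synth) * len(config.columns), 1)
    validity = 1.0 - validation["n_violations"] / n_cells
    structure = validation["structure"]["score"]
    quality = 0.5 * (column_shapes + pair_trends)
    diagnostic = 0.5 * (validity + structure)
    return {
        "column_shape_scores": shapes,
        "column_shapes": column_shapes,
        "pair_trends": pair_trends,
        "quality_score": quality,
        "validity_score": validity,
        "structure_score": structure,
        "diagnostic_score": diagnostic,
    }


# ---------------------------------------------------------------------------
# ML utility


def _classifiers(class_weight: Optional[str]) -> dict[str, Any]:
    return {
        "logistic": LogisticRegression(max_iter=2000, class_weight=class_weight),
        "svm": LinearSVC(class_weight=class_weight),
        "gbt": HistGradientBoostingClassifier(
            max_iter=150, random_state=0, class_weight="balanced"
            if class_weight else None
        ),
    }


def g_mean(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Geometric mean of per-class recalls; 0 if any class is fully missed."""
    recalls = recall_score(y_true, y_pred, average=None, zero_division=0)
    if (recalls == 0).any():
        return 0.0
    return float(stats.gmean(recalls))


def tstr_evaluate(
    synth_train: pd.DataFrame,
    real_test: pd.DataFrame,
    target_column: str,
    feature_columns: Optional[Sequence[str]] = None,
    class_weight: Optional[str] = "balanced",
) -> dict[str, Any]:
    """Train class-weighted classifiers on synthetic rows, test on real rows.

    Features default to all numeric columns except the target.  Returns
    weighted precision/recall/F1 and G-mean per classifier plus the mean
    across classifiers.
    """
    feats = list(feature_columns) if feature_columns else [
        c
        for c in synth_train.columns
        if c != target_column and pd.api.types.is_numeric_dtype(synth_train[c])
    ]
    Xtr = synth_train[feats].to_numpy(float)
    ytr = synth_train[target_column].astype(str).to_numpy()
    Xte = real_test[feats].to_numpy(float)
    yte = real_test[target_column].astype(str).to_numpy()
    if len(np.unique(ytr)) < 2:
        raise ValueError("training data contains a single class")
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
    out: dict[str, Any] = {}
    for name, clf in _classifiers(class_weight).items():
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        p, r, f1, _ = precision_recall_fscore_support(
            yte, pred, average="weighted", zero_division=0
        )
        out[name] = {
            "precision_weighted": float(p),
            "recall_weighted": float(r),
            "f1_weighted": float(f1),
            "g_mean": g_mean(yte, pred),
        }
    out["mean"] = {
        m: float(np.mean([out[c][m] for c in ("logistic", "svm", "gbt")]))
        for m in ("precision_weighted", "recall_weighted", "f1_weighted", "g_mean")
    }
    return out


def augmentation_evaluate(
    real_train: pd.DataFrame,
    synth: pd.DataFrame,
    real_test: pd.DataFrame,
    target_column: str,
    feature_columns: Optional[Sequence[str]] = None,
) -> dict[str, Any]:
    """Metrics for real-only vs real+synthetic training, and their delta."""
    base = tstr_evaluate(real_train, real_test, target_column, feature_columns)
    if len(synth) == 0:
        aug = base
    else:
        combined = pd.concat([real_train, synth], ignore_index=True)
        aug = tstr_evaluate(combined, real_test, target_column, feature_columns)
    delta = {
        m: aug["mean"][m] - base["mean"][m]
        for m in base["mean"]
    }
    return {"real_only": base["mean"], "augmented": aug["mean"], "delta": delta}


# ---------------------------------------------------------------------------
# Friedman + Nemenyi ranking


@dataclass
class RankTable:
    """Average ranks per model with the Nemenyi critical difference."""

    models: list[str]
    average_ranks: dict[str, float]
    critical_difference: float
    per_dataset_ranks: np.ndarray  # (datasets, models)
    alpha: float
    significant_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "models": self.models,
            "average_ranks": self.average_ranks,
            "critical_difference": self.critical_difference,
            "alpha": self.alpha,
            "significant_pairs": [list(p) for p in self.significant_pairs],
        }


def _rank_matrix(scores: np.ndarray, higher_is_better: bool = True) -> np.ndarray:
    """Within-dataset ranks (1 = best), ties averaged."""
    s = scores if higher_is_better else -scores
    return np.apply_along_axis(lambda row: stats.rankdata(-row), 1, s)


def friedman_test(score_matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test across models over datasets.

    ``score_matrix`` is (datasets × models).  Degenerate inputs (fewer
    than 2 models or 2 datasets) are errors; identical scores everywhere
    give statistic 0 and p = 1.
    """
    s = np.asarray(score_matrix, float)
    if s.ndim != 2 or s.shape[1] < 2 or s.shape[0] < 2:
        raise ValueError("need at least 2 models and 2 datasets")
    if np.allclose(s, s[:, :1]):
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*[s[:, j] for j in range(s.shape[1])])
    return float(stat), float(p)


def nemenyi_critical_difference(k: int, N: int, alpha: float = 0.05) -> float:
    """CD = q_α · √(k(k+1)/(6N)) with the studentized-range quantile
    q_α = q_{1−α}(k, ∞)/√2."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = stats.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * N)))


def nemenyi_rank(
    score_matrix: np.ndarray,
    models: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    higher_is_better: bool = True,
) -> RankTable:
    """Average ranks with the Nemenyi critical difference at level alpha."""
    s = np.asarray(score_matrix, float)
    if s.ndim != 2 or s.shape[1] < 2:
        raise ValueError("need at least 2 models")
    N, k = s.shape
    names = list(models) if models else [f"model_{j}" for j in range(k)]
    ranks = _rank_matrix(s, higher_is_better)
    avg = ranks.mean(axis=0)
    cd = nemenyi_critical_difference(k, N, alpha)
    sig = [
        (names[i], names[j])
        for i in range(k)
        for j in range(i + 1, k)
        if abs(avg[i] - avg[j]) > cd
    ]
    return RankTable(
        models=names,
        average_ranks={n: float(r) for n, r in zip(names, avg)},
        critical_difference=cd,
        per_dataset_ranks=ranks,
        alpha=alpha,
        significant_pairs=sig,
    )


def aggregate_rankings(
    family_scores: dict[str, np.ndarray],
    models: Sequence[str],
    failure_mask: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    sentinel_rank: Optional[float] = None,
) -> dict[str, Any]:
    """Pool per-family score matrices into per-family and overall rank tables.

    ``family_scores`` maps family name → (datasets × models) scores
    (higher is better).  Failed (dataset, model) cells — NaN scores or
    True in ``failure_mask`` — receive the sentinel worst rank
    (default n_models + 1) before averaging.
    """
    models = list(models)
    k = len(models)
    sentinel = float(sentinel_rank if sentinel_rank is not None else k + 1)
    per_family: dict[str, RankTable] = {}
    pooled_rank_rows: list[np.ndarray] = []
    for fam, scores in family_scores.items():
        s = np.asarray(scores, float)
        fail = np.isnan(s)
        if failure_mask is not None:
            fail = fail | failure_mask
        filled = np.where(fail, -np.inf, s)
        rt = nemenyi_rank(filled, models, alpha)
        ranks = rt.per_dataset_ranks.copy()
        ranks[fail] = sentinel
        avg = ranks.mean(axis=0)
        rt.average_ranks = {n: float(r) for n, r in zip(models, avg)}
        rt.per_dataset_ranks = ranks
        per_family[fam] = rt
        pooled_rank_rows.append(ranks)
    pooled = np.vstack(pooled_rank_rows)
    overall_avg = pooled.mean(axis=0)
    cd = nemenyi_critical_difference(k, pooled.shape[0], alpha)
    overall = {
        "average_ranks": {n: float(r) for n, r in zip(models, overall_avg)},
        "critical_difference": cd,
        "sentinel_rank": sentinel,
    }
    return {
        "per_family": {f: rt.to_dict() for f, rt in per_family.items()},
        "overall": overall,
    }
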