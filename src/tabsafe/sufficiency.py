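"""Data-sufficiency analysis: how many training rows are enough?

Generative models are fitted on nested subsamples of increasing size;
each fit is scored with the statistical, ML-utility and privacy metric
families, and the score-versus-size curve is examined for the knee
(elbow) where performance plateaus — the minimum sufficient sample size.

Two aggregation routes lead to the elbow:

* the ranking route converts per-size scores to Nemenyi average ranks
  across models/metrics and finds the knee of the rank curve;
* the composite route min-max normalises each metric into [0, 1] within
  declared (worst, best) threshold ranges, orientation-aligned so higher
  is always better, averages them, and finds the knee of the composite.

Knee detection fits a cubic smoothing spline and applies the kneedle
procedure: normalise both axes to [0, 1], form the difference curve
between the (rotated) curve and the chord, and take the interior local
maximum that beats the sensitivity-scaled threshold.  A curve with no
knee (e.g. a straight line) is reported as absent, never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline

from .evaluate import nemenyi_rank

__all__ = [
    "size_grid",
    "detect_elbow",
    "ranking_threshold",
    "composite_threshold",
    "SufficiencyCurve",
    "evaluate_at_sizes",
]


def size_grid(n_total: int, start: int = 1000, cap: int = 70_000) -> list[int]:
    """Sample-size grid: steps of 500 up to 5000, then steps of 5000.

    Starts at ``start`` and is capped at min(n_total, cap); the final
    available size is always included so the full data point anchors the
    curve.
    """
    if start > n_total:
        raise ValueError(f"start={start} exceeds n_total={n_total}")
    top = min(n_total, cap)
    sizes = []
    s = start
    while s <= top:
        sizes.append(s)
        s += 500 if s < 5000 else 5000
    if sizes[-1] != top:
        sizes.append(top)
    return sizes


# ---------------------------------------------------------------------------
# knee detection (kneedle with spline smoothing)


def _smooth(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if len(x) < 5:
        return y
    spl = UnivariateSpline(x, y, k=3, s=len(x) * np.var(y) * 0.05)
    return spl(x)


def detect_elbow(
    x: Sequence[float],
    y: Sequence[float],
    sensitivity: float = 1.0,
    smooth: bool = True,
) -> Optional[float]:
    """Locate the knee of a performance-vs-size curve, or None if absent.

    Invariant to affine rescaling of y; direction (increasing/decreasing)
    and curvature (concave/convex) are auto-detected from the smoothed
    series.
    """
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if len(xa) < 4:
        raise ValueError("need at least 4 points for knee detection")
    if np.any(np.diff(xa) <= 0):
        raise ValueError("x must be strictly increasing")
    ys = _smooth(xa, ya) if smooth else ya.copy()
    span = ys.max() - ys.min()
    if span <= 1e-12 * max(1.0, float(np.abs(ys).max())):
        return None
    xn = (xa - xa.min()) / (xa.max() - xa.min())
    yn = (ys - ys.min()) / span
    if yn[-1] < yn[0]:  # decreasing curve: flip so the knee is a maximum
        yn = 1.0 - yn
    # concave curves bow above the chord; convex below — flip convex ones
    chord = xn
    diff = yn - chord
    if np.abs(diff.min()) > np.abs(diff.max()):
        diff = -diff
    # interior local maxima of the difference curve
    candidates = [
        i
        for i in range(1, len(diff) - 1)
        if diff[i] >= diff[i - 1] and diff[i] >= diff[i + 1]
    ]
    if not candidates:
        return None
    threshold = sensitivity * np.mean(np.abs(np.diff(xn)))
    best = max(candidates, key=lambda i: diff[i])
    if diff[best] < threshold:
        return None
    return float(xa[best])


# ---------------------------------------------------------------------------
# curves and aggregation


@dataclass
class SufficiencyCurve:
    """Scores per (size, model, metric) plus derived series and elbow."""

    sizes: list[int]
    # scores[metric][model] = list aligned with sizes; higher is better
    scores: dict[str, dict[str, list[float]]]
    seeds: list[int] = field(default_factory=list)
    elbow: Optional[float] = None
    aggregated: Optional[list[float]] = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "sizes": self.sizes,
            "scores": self.scores,
            "seeds": self.seeds,
            "elbow": self.elbow,
            "aggregated": self.aggregated,
        }


def evaluate_at_sizes(
    cohort,
    generator: Callable[[Any, int, int], Any],
    metric_suite: Callable[[Any, Any], dict[str, float]],
    grid: Sequence[int],
    seed: int = 0,
    model_name: str = "copula",
) -> SufficiencyCurve:
    """Fit/score a generator on nested subsamples of each grid size.

    ``generator(subsample, n, seed)`` returns a synthetic table of ~n
    rows; ``metric_suite(real, synth)`` returns named scores (higher is
    better).  A generator failure at one size records NaN scores for
    that size instead of raising.
    """
    rng = np.random.default_rng(seed)
    scores: dict[str, dict[str, list[float]]] = {}
    seeds: list[int] = []
    for n in grid:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        seeds.append(sub_seed)
        idx = np.random.default_rng(sub_seed).choice(
            len(cohort), size=min(n, len(cohort)), replace=False
        )
        sub = cohort.iloc[np.sort(idx)].reset_index(drop=True)
        try:
            synth = generator(sub, len(sub), sub_seed)
            result = metric_suite(sub, synth)
        except Exception:
            result = {}
        for metric in set(scores) | set(result):
            scores.setdefault(metric, {}).setdefault(model_name, [])
        for metric, series in scores.items():
            val = result.get(metric, float("nan"))
            series[model_name].append(float(val))
        # backfill metrics that appeared late
        for metric in scores:
            col = scores[metric][model_name]
            while len(col) < len(seeds):
                col.insert(0, float("nan"))
    return SufficiencyCurve(sizes=list(grid), scores=scores, seeds=seeds)


def ranking_threshold(
    curve: SufficiencyCurve, sensitivity: float = 1.0
) -> Optional[float]:
    """Elbow of the Nemenyi-average-rank-versus-size series.

    Sizes play the role of treatments being ranked; (model, metric)
    pairs are the blocks.  All-identical scores give a flat rank curve
    and no elbow.
    """
    sizes = curve.sizes
    if len(sizes) < 2:
        raise ValueError("need at least 2 sizes")
    rows = []
    for metric, per_model in curve.scores.items():
        for model, series in per_model.items():
            if not np.any(np.isnan(series)):
                rows.append(series)
    if not rows:
        return None
    mat = np.asarray(rows, float)  # (blocks, sizes)
    rt = nemenyi_rank(mat, models=[str(s) for s in sizes], higher_is_better=True)
    ranks = [rt.average_ranks[str(s)] for s in sizes]
    curve.aggregated = ranks
    if len(set(np.round(ranks, 12))) == 1:
        curve.elbow = None
        return None
    if len(sizes) < 4:
        raise ValueError("need at least 4 sizes for knee detection")
    curve.elbow = detect_elbow(sizes, ranks, sensitivity)
    return curve.elbow


def composite_threshold(
    curve: SufficiencyCurve,
    threshold_ranges: dict[str, tuple[float, float]],
    sensitivity: float = 1.0,
) -> Optional[float]:
    """Elbow of the normalised composite-score-versus-size series.

    ``threshold_ranges[metric] = (worst, best)``; worst > best encodes a
    lower-is-better metric, and normalisation maps every metric onto
    [0, 1] with 1 = best so the composite mean respects orientation.
    """
    comps = []
    for metric, per_model in curve.scores.items():
        if metric not in threshold_ranges:
            raise KeyError(f"no threshold range declared for metric {metric!r}")
        worst, best = threshold_ranges[metric]
        if worst == best:
            raise ValueError(f"degenerate threshold range for {metric!r}")
        for model, series in per_model.items():
            arr = (np.asarray(series, float) - worst) / (best - worst)
            comps.append(np.clip(arr, 0.0, 1.0))
    composite = np.nanmean(np.vstack(comps), axis=0)
    curve.aggregated = composite.tolist()
    if np.allclose(composite, composite[0]):
        curve.elbow = None
        return None
    curve.elbow = detect_elbow(curve.sizes, composite, sensitivity)
    return curve.elbow
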