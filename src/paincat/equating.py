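"""Single-group equipercentile equating and linear score crosswalks.

Percentile ranks use the plus-half convention PR(x) = 100 (F(x-1) + f(x)/2).
The equipercentile function maps a source score to the target score with the
same percentile rank by linear interpolation of the discrete rank function.
Linear crosswalks are weighted least-squares fits to the equipercentile
concordance; applying one uses spreadsheet ROUND semantics (half away from
zero) followed by clamping to the target range.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoreDistribution",
    "Crosswalk",
    "percentile_ranks",
    "equipercentile_equate",
    "fit_linear_crosswalk",
    "apply_crosswalk",
    "round_trip_report",
    "round_half_away",
    "equate_from_pairs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreDistribution:
    """Frequencies of integer raw scores over a contiguous range."""

    min_score: int
    max_score: int
    frequencies: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.max_score < self.min_score:
            raise ValueError("score range inverted")
        freqs = tuple(int(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if len(freqs) != self.max_score - self.min_score + 1:
            raise ValueError("frequency vector does not cover the score range")
        if any(f < 0 for f in freqs):
            raise ValueError("negative frequency")
        if sum(freqs) == 0:
            raise ValueError("empty score distribution")

    @classmethod
    def from_scores(
        cls, scores, min_score: int | None = None, max_score: int | None = None
    ) -> "ScoreDistribution":
        arr = np.asarray(scores)
        arr = arr[~pd.isna(arr)].astype(int)
        if arr.size == 0:
            raise ValueError("no scores")
        lo = int(arr.min()) if min_score is None else int(min_score)
        hi = int(arr.max()) if max_score is None else int(max_score)
        if np.any(arr < lo) or np.any(arr > hi):
            raise ValueError("scores outside the declared range")
        freqs = np.bincount(arr - lo, minlength=hi - lo + 1)
        return cls(lo, hi, tuple(int(f) for f in freqs))

    @property
    def scores(self) -> np.ndarray:
        return np.arange(self.min_score, self.max_score + 1)

    @property
    def total(self) -> int:
        return sum(self.frequencies)


@dataclass(frozen=True)
class Crosswalk:
    """Linear raw-score conversion ``target = ROUND(intercept + slope * source)``."""

    source: str
    target: str
    intercept: float
    slope: float
    source_range: tuple[int, int]
    target_range: tuple[int, int]
    clamp: bool = True
    residual_rmse: float = float("nan")
    residual_max: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("crosswalk slope must be nonzero")


def round_half_away(x: float) -> int:
    """Spreadsheet ROUND(x; 0): halves round away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percentile_ranks(dist: ScoreDistribution) -> np.ndarray:
    """Plus-half percentile rank of every integer score in the range."""
    f = np.asarray(dist.frequencies, dtype=float)
    n = f.sum()
    below = np.concatenate([[0.0], np.cumsum(f)[:-1]])
    return 100.0 * (below + 0.5 * f) / n


def _inverse_rank(dist: ScoreDistribution, pr: float) -> float:
    """Continuized inverse of the percentile-rank function (Kolen-Brennan).

    Treats score x as the interval [x - 0.5, x + 0.5) carrying f(x)/N of the
    probability mass and inverts the piecewise-linear CDF.
    """
    f = np.asarray(dist.frequencies, dtype=float)
    n = f.sum()
    # tiny backoff keeps exact-boundary ranks on the lower score despite
    # floating-point rounding of the cumulative sums
    p = pr / 100.0 - 1e-12
    cum = np.cumsum(f) / n  # F(x) at upper edge x + 0.5
    scores = dist.scores
    if p <= 0:
        return float(scores[0] - 0.5)
    if p >= 1:
        return float(scores[-1] + 0.5)
    idx = int(np.searchsorted(cum, p, side="left"))
    idx = min(idx, len(scores) - 1)
    lower_cum = cum[idx - 1] if idx > 0 else 0.0
    share = f[idx] / n
    if share <= 0:
        # no mass at this score: land at its lower edge
        return float(scores[idx] - 0.5)
    frac = (p - lower_cum) / share
    return float(scores[idx] - 0.5 + frac)


def equipercentile_equate(
    x_dist: ScoreDistribution, y_dist: ScoreDistribution
) -> pd.DataFrame:
    """Equate every source score to the target score with equal percentile rank.

    Returns a frame with columns ``score``, ``percentile_rank`` and
    ``equated`` (continuous, monotone nondecreasing).
    """
    if len(np.flatnonzero(y_dist.frequencies)) == 1:
        warnings.warn("degenerate target distribution: constant concordance",
                      stacklevel=2)
    prs = percentile_ranks(x_dist)
    equated = np.array([_inverse_rank(y_dist, pr) for pr in prs])
    equated = np.maximum.accumulate(equated)  # guard against float wiggle
    return pd.DataFrame(
        {"score": x_dist.scores, "percentile_rank": prs, "equated": equated}
    )


def fit_linear_crosswalk(
    equated: pd.DataFrame,
    weights=None,
    source: str = "X",
    target: str = "Y",
    source_range: tuple[int, int] | None = None,
    target_range: tuple[int, int] | None = None,
    clamp: bool = True,
) -> Crosswalk:
    """Weighted least-squares line through an equipercentile concordance.

    ``equated`` is the output of :func:`equipercentile_equate`; ``weights``
    default to the source score frequencies when present, else uniform.
    """
    x = equated["score"].to_numpy(dtype=float)
    y = equated["equated"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct source scores")
    if np.allclose(y, y[0]):
        raise ValueError("constant concordance: no linear crosswalk exists")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w < 0) or w.sum() == 0:
        raise ValueError("invalid weights")
    wm = w / w.sum()
    xbar, ybar = wm @ x, wm @ y
    sxx = wm @ (x - xbar) ** 2
    sxy = wm @ ((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    rmse = float(np.sqrt(wm @ resid**2))
    return Crosswalk(
        source=source,
        target=target,
        intercept=float(intercept),
        slope=float(slope),
        source_range=source_range or (int(x.min()), int(x.max())),
        target_range=target_range or (int(np.floor(y.min())), int(np.ceil(y.max()))),
        clamp=clamp,
        residual_rmse=rmse,
        residual_max=float(np.max(np.abs(resid))),
    )


def apply_crosswalk(cw: Crosswalk, score: int) -> int:
    """Convert one raw score through the crosswalk (ROUND then clamp)."""
    lo, hi = cw.source_range
    if not lo <= score <= hi:
        raise ValueError(f"score {score} outside source range [{lo}, {hi}]")
    raw = cw.intercept + cw.slope * score
    out = round_half_away(raw)
    if cw.clamp:
        out = int(np.clip(out, cw.target_range[0], cw.target_range[1]))
    return out


def round_trip_report(
    cw_xy: Crosswalk, cw_yx: Crosswalk, x_range: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Per-score |x - back-converted x| over the source range, with summary.

    The frame's ``attrs`` carry ``max_discrepancy`` and ``mean_discrepancy``.
    """
    rng = x_range or cw_xy.source_range
    if rng[0] < cw_xy.source_range[0] or rng[1] > cw_xy.source_range[1]:
        raise ValueError("x_range outside the forward crosswalk's source range")
    rows = []
    for x in range(rng[0], rng[1] + 1):
        y = apply_crosswalk(cw_xy, x)
        y_in = int(np.clip(y, cw_yx.source_range[0], cw_yx.source_range[1]))
        back = apply_crosswalk(cw_yx, y_in)
        rows.append({"score": x, "converted": y, "back": back, "discrepancy": abs(x - back)})
    df = pd.DataFrame(rows)
    df.attrs["max_discrepancy"] = int(df["discrepancy"].max())
    df.attrs["mean_discrepancy"] = float(df["discrepancy"].mean())
    return df


def equate_from_pairs(
    pairs: pd.DataFrame,
    x_col: str,
    y_col: str,
    x_range: tuple[int, int] | None = None,
    y_range: tuple[int, int] | None = None,
    min_group: int = 20,
) -> tuple[Crosswalk, Crosswalk, pd.DataFrame]:
    """Full single-group equating of paired raw totals: both crosswalks.

    Complete cases only; warns for samples below ``min_group`` (group-level
    use only).  Returns (x->y crosswalk, y->x crosswalk, concordance table).
    """
    df = pairs[[x_col, y_col]].dropna()
    if len(df) < min_group:
        warnings.warn(
            f"only {len(df)} complete pairs; crosswalks are intended for "
            f"groups of {min_group}+ individuals",
            stacklevel=2,
        )
    xd = ScoreDistribution.from_scores(
        df[x_col], *(x_range or (None, None))
    )
    yd = ScoreDistribution.from_scores(
        df[y_col], *(y_range or (None, None))
    )
    conc_xy = equipercentile_equate(xd, yd)
    conc_yx = equipercentile_equate(yd, xd)
    cw_xy = fit_linear_crosswalk(
        conc_xy,
        weights=np.asarray(xd.frequencies, dtype=float),
        source=x_col,
        target=y_col,
        source_range=(xd.min_score, xd.max_score),
        target_range=(yd.min_score, yd.max_score),
    )
    cw_yx = fit_linear_crosswalk(
        conc_yx,
        weights=np.asarray(yd.frequencies, dtype=float),
        source=y_col,
        target=x_col,
        source_range=(yd.min_score, yd.max_score),
        target_range=(xd.min_score, xd.max_score),
    )
    conc = conc_xy.rename(columns={"score": x_col, "equated": f"equated_{y_col}"})
    conc["rounded"] = [apply_crosswalk(cw_xy, int(s)) for s in conc[x_col]]
    return cw_xy, cw_yx, conc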