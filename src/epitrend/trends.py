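"""Per-gene trend fits, tightness statistics and 10-type classification.

With embryos in developmental order, each expressed gene's profile is
smoothed by lowess (span 2/3, 3 robustness iterations) and fitted by a
line over developmental rank.  From these come:

* DTFL — the median absolute distance of samples to the lowess fit, the
  tightness-of-regulation statistic;
* the angle of the linear fit (rank vs log2 intensity), classifying
  profiles as increasing (> 0.1 deg), decreasing (< -0.1 deg) or flat;
* the continuity ratio mean|y - lowess| / mean|y - linear|: values above
  0.95 mean the curve offers little over the line (continuous change);
* edge presence tests: a gene whose reporting probe is 'present' in
  fewer than 7 of the 15 first (last) ordered embryos switches on (off)
  within the window;
* an autocorrelation score flagging oscillatory profiles.

A decision tree combines these into ten exclusive profile types, and
linear slopes convert to fold change per hour via the linear pseudotime
map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

#: the ten profile categories, in type-number order (1..10)
CATEGORIES = (
    "down_off",          # 1: switched off inside the window
    "down_stop",         # 2: decreasing, stop point located geometrically
    "down_continuous",   # 3: gradual linear decrease
    "down_discontinuous",  # 4: two-phase decrease
    "constant",          # 5
    "up_discontinuous",  # 6: two-phase increase
    "up_continuous",     # 7: gradual linear increase
    "up_start",          # 8: increasing, start point located geometrically
    "up_on",             # 9: switched on inside the window
    "oscillatory",       # 10
)

#: default category -> type-number map (configurable in the classifier)
TYPE_NUMBER: dict[str, int] = {name: i + 1 for i, name in enumerate(CATEGORIES)}

FAMILY = {
    "down_off": "down", "down_stop": "down", "down_continuous": "down",
    "down_discontinuous": "down", "constant": "constant",
    "up_discontinuous": "up", "up_continuous": "up", "up_start": "up",
    "up_on": "up", "oscillatory": "oscillatory",
}

ANGLE_THRESHOLD_DEG = 0.1
CONTINUITY_THRESHOLD = 0.95
EDGE_WINDOW = 15
EDGE_MAX_PRESENT = 7  # 'fewer than 7 of 15' present
LOWESS_SPAN = 2.0 / 3.0


@dataclass
class TrendFit:
    """Lowess and linear fits of one ordered profile plus summary stats."""

    lowess_values: np.ndarray
    linear_slope: float  # log2 per rank-unit
    linear_intercept: float
    angle_deg: float
    dtfl: float
    continuity_ratio: float


@dataclass
class GeneClassification:
    category: str
    type_number: int
    fc_per_hour: float
    starting: bool = False
    stopping: bool = False


def lowess_trend(profile: Sequence[float], span: float = LOWESS_SPAN, iterations: int = 3) -> np.ndarray:
    """Robust locally weighted regression over developmental rank."""
    y = np.asarray(profile, dtype=float)
    if np.ptp(y) == 0:
        return y.copy()
    x = np.arange(1.0, y.size + 1.0)
    return _sm_lowess(y, x, frac=span, it=iterations, return_sorted=False)


def dtfl(profile: Sequence[float], fitted: Sequence[float]) -> float:
    """Median absolute distance of the samples to the fitted line."""
    y = np.asarray(profile, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if y.shape != f.shape:
        raise ValueError("profile and fitted values must have the same length")
    return float(np.median(np.abs(y - f)))


def linear_fit(profile: Sequence[float]) -> tuple[float, float, np.ndarray]:
    """Least-squares line over rank 1..n; returns (slope, intercept, fitted)."""
    y = np.asarray(profile, dtype=float)
    x = np.arange(1.0, y.size + 1.0)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept), slope * x + intercept


def angle_classify(profile: Sequence[float]) -> tuple[str, float]:
    """Direction label from the slope angle of the linear fit.

    x is developmental rank with unit spacing; angle = atan(slope) in
    degrees.  Strictly above 0.1 deg -> increasing, strictly below
    -0.1 deg -> decreasing, otherwise flat (boundary values are flat).
    """
    slope, _, _ = linear_fit(profile)
    angle = math.degrees(math.atan(slope))
    if angle > ANGLE_THRESHOLD_DEG:
        return "increasing", angle
    if angle < -ANGLE_THRESHOLD_DEG:
        return "decreasing", angle
    return "flat", angle


def continuity_ratio(profile: Sequence[float], linear_fitted: Sequence[float],
                     lowess_fitted: Sequence[float]) -> tuple[float, str]:
    """mean|y - lowess| / mean|y - linear|, with 'continuous' for ratios
    strictly above 0.95 (a ratio of exactly 0.95 is discontinuous).  A
    perfectly linear profile (zero linear residual) is continuous with
    ratio 1."""
    y = np.asarray(profile, dtype=float)
    d_lin = float(np.mean(np.abs(y - np.asarray(linear_fitted, dtype=float))))
    d_low = float(np.mean(np.abs(y - np.asarray(lowess_fitted, dtype=float))))
    if d_lin == 0.0:
        return 1.0, "continuous"
    ratio = d_low / d_lin
    return ratio, ("continuous" if ratio > CONTINUITY_THRESHOLD else "discontinuous")


def fit_trend(profile: Sequence[float]) -> TrendFit:
    """All fits and summary statistics for one ordered profile."""
    y = np.asarray(profile, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 ordered samples to fit a trend")
    low = lowess_trend(y)
    slope, intercept, lin = linear_fit(y)
    ratio, _ = continuity_ratio(y, lin, low)
    return TrendFit(
        lowess_values=low,
        linear_slope=slope,
        linear_intercept=intercept,
        angle_deg=math.degrees(math.atan(slope)),
        dtfl=dtfl(y, low),
        continuity_ratio=ratio,
    )


def representative_probe(gene: str, transcript_matrix: pd.DataFrame,
                         annotation: pd.DataFrame, presence_mask: pd.DataFrame) -> str:
    """The probe that reports a gene's presence: the most 3' probe with
    any 'present' call on the transcript of the gene with the highest
    expression.  ``three_prime_rank`` counts from the 3' end (1 = most 3')."""
    ann = annotation[annotation["gene_id"] == gene]
    if ann.empty:
        raise KeyError(f"gene {gene!r} absent from annotation")
    tx_ids = [t for t in ann["transcript_id"].unique() if t in transcript_matrix.index]
    if not tx_ids:
        raise KeyError(f"gene {gene!r} has no transcript in the expression matrix")
    best_tx = max(tx_ids, key=lambda t: transcript_matrix.loc[t].mean())
    probes = ann[ann["transcript_id"] == best_tx].sort_values("three_prime_rank")
    probes = probes[probes["probe_id"].isin(presence_mask.index)]
    if probes.empty:
        raise KeyError(f"transcript {best_tx!r} has no probes in the presence mask")
    with_calls = probes[presence_mask.loc[probes["probe_id"]].any(axis=1).to_numpy()]
    chosen = with_calls if not with_calls.empty else probes
    return str(chosen.iloc[0]["probe_id"])


def edge_presence_test(gene: str, presence_mask: pd.DataFrame, annotation: pd.DataFrame,
                       transcript_matrix: pd.DataFrame, order: Sequence[str],
                       side: str) -> bool:
    """True when the gene's reporting probe is 'present' in fewer than 7
    of the 15 edge embryos (``side`` = 'first' or 'last'), i.e. the gene
    is switching on (off) within the sampled window."""
    if side not in ("first", "last"):
        raise ValueError("side must be 'first' or 'last'")
    probe = representative_probe(gene, transcript_matrix, annotation, presence_mask)
    edge = list(order[:EDGE_WINDOW]) if side == "first" else list(order[-EDGE_WINDOW:])
    n_present = int(presence_mask.loc[probe, edge].sum())
    return n_present < EDGE_MAX_PRESENT


def oscillation_score(profile: Sequence[float], lowess_fitted: Sequence[float] | None = None,
                      min_lag: int = 5, threshold: float = 0.5,
                      override: Iterable[str] = (), gene: str | None = None) -> tuple[float, bool]:
    """Oscillation score of lowess-detrended residuals.

    The autocorrelation of the residuals is computed over lags
    ``min_lag`` .. n/3; the score is the maximum, over candidate periods
    L, of acf(L) - acf(L/2).  A genuine oscillation has a positive peak
    at its period and a negative trough at half the period, so the
    contrast approaches twice the signal fraction; smooth non-periodic
    residual structure (e.g. a switch-shaped bend the trend fit cannot
    follow) has a monotonically decaying acf and scores near or below
    zero.  Oscillatory when the score reaches ``threshold`` or the gene
    is on the curated override list (mirroring oscillators confirmed
    from the literature).
    """
    y = np.asarray(profile, dtype=float)
    if gene is not None and gene in set(override):
        return float("nan"), True
    if lowess_fitted is None:
        lowess_fitted = lowess_trend(y)
    r = y - np.asarray(lowess_fitted, dtype=float)
    r = r - r.mean()
    denom = float(np.dot(r, r))
    if denom == 0:
        return 0.0, False
    n = r.size
    max_lag = n // 3
    if max_lag < 2 * min_lag:
        return 0.0, False
    acf = {lag: float(np.dot(r[:-lag], r[lag:]) / denom) for lag in range(min_lag, max_lag + 1)}
    score = max(
        acf[lag] - acf[max(lag // 2, min_lag)] for lag in range(2 * min_lag, max_lag + 1)
    )
    return score, score >= threshold


def classify_gene(trend: TrendFit, edge_on: bool, edge_off: bool,
                  start_valid: bool, stop_valid: bool, oscillatory: bool,
                  n_samples: int, t_start: float = 5.0, t_end: float = 8.0,
                  type_map: Mapping[str, int] | None = None) -> GeneClassification:
    """Total decision tree over the ten profile types.

    oscillatory -> 10; flat -> 5; increasing: switched on at the early
    edge -> 9, else a valid geometric start point -> 8, else continuous
    -> 7, else -> 6; decreasing: switched off at the late edge -> 1,
    else a valid stop point -> 2, else continuous -> 3, else -> 4.
    """
    type_map = dict(type_map or TYPE_NUMBER)
    angle = trend.angle_deg
    continuous = trend.continuity_ratio > CONTINUITY_THRESHOLD
    if oscillatory:
        cat = "oscillatory"
    elif abs(angle) <= ANGLE_THRESHOLD_DEG:
        cat = "constant"
    elif angle > ANGLE_THRESHOLD_DEG:
        if edge_on:
            cat = "up_on"
        elif start_valid:
            cat = "up_start"
        elif continuous:
            cat = "up_continuous"
        else:
            cat = "up_discontinuous"
    else:
        if edge_off:
            cat = "down_off"
        elif stop_valid:
            cat = "down_stop"
        elif continuous:
            cat = "down_continuous"
        else:
            cat = "down_discontinuous"
    fc = fc_per_hour(trend.linear_slope, n_samples, t_start, t_end)
    return GeneClassification(
        category=cat,
        type_number=type_map[cat],
        fc_per_hour=fc,
        starting=cat in ("up_start", "up_on"),
        stopping=cat in ("down_stop", "down_off"),
    )


def fc_per_hour(slope_per_rank: float, n_samples: int,
                t_start: float = 5.0, t_end: float = 8.0) -> float:
    """Fold change per hour from a log2 slope per rank-unit under the
    linear rank -> hpf pseudotime map; always >= 1."""
    ranks_per_hour = (n_samples - 1) / (t_end - t_start)
    return float(2.0 ** (abs(slope_per_rank) * ranks_per_hour))
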