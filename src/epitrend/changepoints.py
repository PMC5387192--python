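"""Geometric location of expression start and stop points.

Switching profiles approach their off level with a shrinking rate of
change (a concave form), so a lowess curve and a straight line fitted to
the full ordered profile diverge most where the switch happens.  The
locator exploits this: the two samples where lowess and line (nearly)
intersect bracket the region of interest, the sample of maximal
divergence between them (L1) marks the bend, and a second line fitted to
the steep side of L1 is extrapolated until it meets the off level - the
plateau of 'not-present' probe intensities at the relevant edge of the
series.  The crossing must close to within a small tolerance (0.05 log2
units by default) for the point to count.

For genes already expressed at the window start, the fitted rate instead
extrapolates a predicted onset backwards in time, possibly before
spawning (0 hpf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trends import EDGE_WINDOW, linear_fit, lowess_trend

CLOSURE_TOLERANCE = 0.05  # log2 units


@dataclass
class ChangePoint:
    kind: str  # 'start' or 'stop'
    rank_estimate: int | None  # 1-based developmental rank
    hpf_estimate: float | None
    off_level: float
    valid: bool
    closure_gap: float  # min |lf2 - off_level| over the discrete ranks
    l1_index: int | None = None  # 1-based rank of maximal lowess/line divergence
    off_level_fallback: bool = False
    lf2_slope: float = float("nan")  # the extrapolated fit, log2 per rank
    lf2_intercept: float = float("nan")


def off_level_from_presence(probe_values: pd.Series, present: pd.Series,
                            order: Sequence[str], kind: str) -> tuple[float, bool]:
    """Median intensity of the reporting probe's 'not-present'
    observations in the 15 edge embryos (first for a start, last for a
    stop).  Falls back, flagged, to the global median of not-present
    intensities when the edge window has none."""
    if kind not in ("start", "stop"):
        raise ValueError("kind must be 'start' or 'stop'")
    edge = list(order[:EDGE_WINDOW]) if kind == "start" else list(order[-EDGE_WINDOW:])
    absent_edge = [e for e in edge if not bool(present.loc[e])]
    if absent_edge:
        return float(probe_values.loc[absent_edge].median()), False
    absent_all = [e for e in order if not bool(present.loc[e])]
    if not absent_all:
        raise ValueError("probe is 'present' everywhere; no off level to infer")
    return float(probe_values.loc[absent_all].median()), True


def off_level_from_profile(profile: Sequence[float], present_ordered: Sequence[bool],
                           kind: str) -> tuple[float, bool]:
    """Off level on the scale of the (normalised, summarised) gene
    profile itself: the median of the profile values at the edge embryos
    whose reporting probe is 'not-present'.

    Keeping profile and off level on one scale is what makes the closure
    tolerance meaningful; the probe-intensity variant
    (:func:`off_level_from_presence`) is available where raw intensities
    are wanted.  Absence gates the estimate - an off plateau exists only
    where 'not-present' calls occur - but the level itself is the median
    over all observations of the edge window: for a plateau near the
    detection boundary, conditioning the median on the absent calls
    alone would select the noise's lower tail and bias the off level
    downward.  When the first 15 embryos contain no absent call the
    window is extended, flagged, to the nearest one.
    """
    if kind not in ("start", "stop"):
        raise ValueError("kind must be 'start' or 'stop'")
    y = np.asarray(profile, dtype=float)
    absent = ~np.asarray(present_ordered, dtype=bool)
    if not absent.any():
        raise ValueError("probe is 'present' everywhere; no off level to infer")
    a = absent if kind == "start" else absent[::-1]
    v = y if kind == "start" else y[::-1]
    first_absent = int(np.nonzero(a)[0][0])
    # the smallest edge window containing a 'not-present' call; for a
    # plateau hovering just above the boundary the nearest absent call
    # may lie outside the first 15 embryos
    m = max(EDGE_WINDOW, first_absent + 1)
    fallback = first_absent >= EDGE_WINDOW
    return float(np.median(v[:m])), fallback


LOCATOR_SPAN = 0.4  # lowess span for the locator's curve fit; see note below


def locate_changepoint(profile: Sequence[float], off_level: float, kind: str,
                       tolerance: float = CLOSURE_TOLERANCE,
                       lowess_fitted: Sequence[float] | None = None,
                       t_start: float = 5.0, t_end: float = 8.0,
                       lf2_side: str = "methods", span: float = LOCATOR_SPAN) -> ChangePoint:
    """Locate the rank at which a switching gene leaves or reaches its
    off level.

    Steps: (1) fit a line (lf1) and a lowess curve (lof1) to the full
    profile; (2) the two ranks of smallest |lof1 - lf1| are the crossing
    points and the rank of largest divergence between them is L1;
    (3) a second line lf2 is fitted to ranks 1..L1 for a stop and L1..n
    for a start (``lf2_side='swapped'`` exchanges the two ranges);
    (4) the change point is the rank minimising |lf2(rank) - off_level|
    over all n ranks, valid only when that minimum is below
    ``tolerance``.  hpf estimates use the linear rank -> hpf map.

    The locator's lowess uses a span of 0.4 rather than the 2/3 used for
    trend statistics: with a span of 2/3 the curve is too stiff to bend
    around a switch in the outer third of the window, leaving the
    curve-line difference single-signed so that no crossing pair exists.
    """
    if kind not in ("start", "stop"):
        raise ValueError("kind must be 'start' or 'stop'")
    if lf2_side not in ("methods", "swapped"):
        raise ValueError("lf2_side must be 'methods' or 'swapped'")
    y = np.asarray(profile, dtype=float)
    n = y.size
    lof1 = (np.asarray(lowess_fitted, dtype=float) if lowess_fitted is not None
            else lowess_trend(y, span=span))
    _, _, lf1 = linear_fit(y)
    diff = lof1 - lf1
    d = np.abs(diff)

    # the crossing points of lowess and line: sign changes of their
    # difference (the samples of smallest |difference|); L1 is the rank
    # of largest divergence between the outermost crossings
    sign_change = np.nonzero(diff[:-1] * diff[1:] <= 0)[0]
    if sign_change.size < 2:
        return ChangePoint(kind, None, None, off_level, False, math.inf)
    i_lo, i_hi = int(sign_change[0]), int(sign_change[-1]) + 1
    if i_hi - i_lo < 2:
        return ChangePoint(kind, None, None, off_level, False, math.inf)
    between = slice(i_lo + 1, i_hi)
    l1 = int(np.argmax(d[between])) + i_lo + 1

    use_late = (kind == "start") == (lf2_side == "methods")
    seg = np.arange(l1, n) if use_late else np.arange(0, l1 + 1)
    if seg.size < 3:
        return ChangePoint(kind, None, None, off_level, False, math.inf, l1 + 1)
    slope, intercept = np.polyfit(seg + 1.0, y[seg], 1)

    ranks = np.arange(1.0, n + 1.0)
    gaps = np.abs(slope * ranks + intercept - off_level)
    best = int(np.argmin(gaps))
    gap = float(gaps[best])
    # a minimiser on the first or last rank means lf2 meets the off level
    # outside the sampled window: the switch is not bracketed
    valid = gap < tolerance and 0 < best < n - 1
    hpf = t_start + (best / (n - 1)) * (t_end - t_start)
    return ChangePoint(
        kind=kind,
        rank_estimate=best + 1,
        hpf_estimate=float(hpf),
        off_level=off_level,
        valid=valid,
        closure_gap=gap,
        l1_index=l1 + 1,
        lf2_slope=float(slope),
        lf2_intercept=float(intercept),
    )


def locate_changepoint_refined(profile: Sequence[float], present_ordered: Sequence[bool],
                               kind: str, tolerance: float = CLOSURE_TOLERANCE,
                               t_start: float = 5.0, t_end: float = 8.0,
                               span: float = LOCATOR_SPAN) -> ChangePoint:
    """Two-pass change-point location with a locally re-measured off level.

    The first pass uses the edge-window off level
    (:func:`off_level_from_profile`).  When it yields a valid interior
    crossing, the off level is re-estimated as the median of the 15
    profile values on the off side of that crossing (ending 5 samples
    short of it, to stay clear of the ease-in) and the crossing is
    recomputed.  Measuring the plateau next to the bend instead of at
    the series edge makes the estimate robust to slow drifts that
    normalisation can impose along the plateau.
    """
    y = np.asarray(profile, dtype=float)
    off, fallback = off_level_from_profile(y, present_ordered, kind)
    first = locate_changepoint(y, off, kind, tolerance, t_start=t_start, t_end=t_end, span=span)
    first.off_level_fallback = fallback
    if not first.valid or first.rank_estimate is None:
        return first
    c = first.rank_estimate - 1  # 0-based
    if kind == "start":
        lo, hi = c - 20, c - 5
    else:
        lo, hi = c + 5, c + 20
    lo, hi = max(lo, 0), min(hi, y.size)
    if hi - lo < 8:
        return first
    local_off = float(np.median(y[lo:hi]))
    # only the horizontal moves in the second pass; the fits stand
    ranks = np.arange(1.0, y.size + 1.0)
    gaps = np.abs(first.lf2_slope * ranks + first.lf2_intercept - local_off)
    best = int(np.argmin(gaps))
    gap = float(gaps[best])
    if not (gap < tolerance and 0 < best < y.size - 1):
        return first
    hpf = t_start + (best / (y.size - 1)) * (t_end - t_start)
    return ChangePoint(
        kind=kind, rank_estimate=best + 1, hpf_estimate=float(hpf), off_level=local_off,
        valid=True, closure_gap=gap, l1_index=first.l1_index, off_level_fallback=fallback,
        lf2_slope=first.lf2_slope, lf2_intercept=first.lf2_intercept,
    )


def extrapolate_start(first_level: float, rate_fc_per_hour: float, off_level: float,
                      t_start: float = 5.0) -> float:
    """Predicted onset (hpf, possibly negative = before spawning) for a
    gene already expressed at the window start: run its exponential rise
    backwards from ``first_level`` until it meets ``off_level``.

    Genes with constant expression have no rate of their own; callers
    supply the dataset's maximum positive rate for those.
    """
    if rate_fc_per_hour <= 1.0:
        raise ValueError("extrapolation requires a rate above 1 FC/hour")
    return t_start - (first_level - off_level) / math.log2(rate_fc_per_hour)
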