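"""Embryo morphometrics from oriented binary masks.

Masks are rasters in which true pixels cover embryo plus yolk, oriented
with the animal-vegetal axis along x (animal pole at low x).  From a
mask and a manually annotated epiboly-front x-coordinate the module
derives the metrics used to stage embryos: height (animal-vegetal
diameter), width, area, perimeter, percentage epiboly (epibolic distance
over height) and roundness (4*pi*Area / Perimeter^2).  The metric with
the largest relative change across a series - in practice percentage
epiboly - is the one worth ordering embryos by.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skimage.measure import find_contours


@dataclass
class EmbryoMask:
    """Binary embryo+yolk raster, animal-vegetal axis along x."""

    raster: np.ndarray  # 2-D boolean, axis 0 = x (animal-vegetal), axis 1 = y
    um_per_pixel: float = 1.0
    av_axis: str = "x"

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2:
            raise ValueError("mask raster must be 2-D")
        if not self.raster.any():
            raise ValueError("mask contains no embryo pixels")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        if self.av_axis != "x":
            raise ValueError("masks must be oriented with the animal-vegetal axis on x")


@dataclass
class ImageMetrics:
    area: float  # um^2
    perimeter: float  # um
    height: float  # um, animal-vegetal diameter
    width: float  # um, perpendicular diameter
    epibolic_distance: float  # um, animal pole to epiboly front
    epiboly_pct: float
    roundness: float  # 4*pi*A / P^2, dimensionless


def load_mask(path: str | Path, um_per_pixel: float = 1.0, threshold: float = 0) -> EmbryoMask:
    """Read a PNG/TIFF image as a binary mask (any channel above
    ``threshold`` counts as embryo)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img.max(axis=-1)
    return EmbryoMask(raster=img > threshold, um_per_pixel=um_per_pixel)


def compute_metrics(mask: EmbryoMask, epiboly_front_x: float) -> ImageMetrics:
    """Morphometrics of one embryo.

    ``epiboly_front_x`` is the pixel x-coordinate of the progressing
    epibolic border (annotated from the photograph).  Height is the x
    extent of the mask, the epibolic distance runs from the animal-pole
    edge (lowest x) to the front, and percentage epiboly is their ratio.
    Perimeter comes from tracing the sub-pixel boundary contour and
    lightly smoothing it, which corrects the staircase overestimate of
    diagonal boundary runs.
    """
    r = mask.raster
    xs, ys = np.nonzero(r)
    x_min, x_max = int(xs.min()), int(xs.max())
    y_min, y_max = int(ys.min()), int(ys.max())
    if not x_min <= epiboly_front_x <= x_max:
        raise ValueError(
            f"epiboly front x={epiboly_front_x} outside the mask extent [{x_min}, {x_max}]"
        )
    um = mask.um_per_pixel
    area = float(r.sum()) * um**2
    perim = _traced_perimeter(r) * um
    height = (x_max - x_min) * um
    width = (y_max - y_min) * um
    epibolic = (float(epiboly_front_x) - x_min) * um
    pct = 100.0 * epibolic / height if height > 0 else 0.0
    roundness = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
    return ImageMetrics(
        area=area,
        perimeter=perim,
        height=height,
        width=width,
        epibolic_distance=epibolic,
        epiboly_pct=pct,
        roundness=float(roundness),
    )


def _traced_perimeter(raster: np.ndarray, smooth_window: int = 5) -> float:
    """Boundary length from marching-squares contours, smoothed with a
    short circular moving average to remove pixel staircase artefacts."""
    total = 0.0
    w = smooth_window
    kernel = np.ones(w) / w
    for c in find_contours(raster.astype(float), 0.5):
        closed = np.allclose(c[0], c[-1])
        pts = c[:-1] if closed else c
        if closed and pts.shape[0] > w:
            sm = np.column_stack([
                np.convolve(np.r_[pts[-(w // 2):, i], pts[:, i], pts[: w // 2, i]],
                            kernel, mode="valid")
                for i in (0, 1)
            ])
            sm = np.vstack([sm, sm[:1]])
        else:
            sm = c
        d = np.diff(sm, axis=0)
        total += float(np.sqrt((d**2).sum(axis=1)).sum())
    return total


def max_relative_change(metric_series: Sequence[float]) -> float:
    """(max - min) / min of a per-embryo metric series."""
    x = np.asarray(metric_series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 embryos")
    lo = float(x.min())
    if lo <= 0:
        raise ValueError("relative change undefined for non-positive minima")
    return float((x.max() - lo) / lo)


def select_ordering_metric(series_by_metric: Mapping[str, Sequence[float]]) -> str:
    """The metric with the largest relative change across the series -
    the best crude marker for ordering embryos."""
    if not series_by_metric:
        raise ValueError("no metric series given")
    return max(series_by_metric, key=lambda k: max_relative_change(series_by_metric[k]))
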