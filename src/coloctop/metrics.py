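"""Colocalization metrics: Pearson's R, Mander's M1/M2, Costes threshold.

The conventions follow the JACoP implementation of these statistics:

* Pearson's R is computed over all pixels of the analysis region, raw,
  with no thresholding or background subtraction.
* Mander's coefficients are channel-intensity fractions:
  ``M1 = sum(red over pixels with green > t_green) / sum(red)`` — the
  overlap of red in pixels that are green — and M2 the same with the
  channels swapped.
* The Costes automatic threshold fits an ordinary least-squares
  regression of green on red, then walks the red threshold down from the
  intensity maximum with ``t_green = a * t_red + b``, stopping at the
  highest threshold for which the pixels *below* both thresholds are
  uncorrelated or anti-correlated (Pearson <= 0).

All images are treated as unsigned-integer rasters; regions are boolean
pixel sets derived from label masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

from .segment import CellMask
from .simulate import FieldOfView

__all__ = ["ColocResult", "CostesFit", "pearson", "costes_threshold",
           "manders", "coloc_per_cell"]


@dataclass
class ColocResult:
    """Per-cell colocalization statistics.

    Undefined quantities (constant channel for Pearson, zero channel sum
    for Mander's) are NaN, with the reason recorded in ``flags`` rather
    than silently reported as 0.
    """

    cell_id: int
    pearson_r: float
    m1: float
    m2: float
    t_red: float
    t_green: float
    n_pixels: int
    flags: tuple[str, ...] = ()

    @property
    def pearson_defined(self) -> bool:
        return np.isfinite(self.pearson_r)

    @property
    def manders_defined(self) -> bool:
        return np.isfinite(self.m1) and np.isfinite(self.m2)


@dataclass
class CostesFit:
    """Result of the Costes automatic threshold search."""

    slope: float
    intercept: float
    t_red: float
    t_green: float
    stop_pearson: float
    flags: tuple[str, ...] = ()


def _region_values(img: np.ndarray, region: Optional[np.ndarray]) -> np.ndarray:
    a = np.asarray(img)
    if region is None:
        return a.ravel().astype(float)
    region = np.asarray(region, dtype=bool)
    if region.shape != a.shape:
        raise ValueError(f"region shape {region.shape} != image shape {a.shape}")
    return a[region].astype(float)


def pearson(red, green, region: Optional[np.ndarray] = None) -> float:
    """Pearson correlation of the two channels over a pixel region.

    Returns NaN when either channel is constant on the region (the
    correlation is undefined); raises on an empty region.
    """
    r = _region_values(red, region)
    g = _region_values(green, region)
    if r.size != g.size:
        raise ValueError("channels differ in size over the region")
    if r.size == 0:
        raise ValueError("empty region: Pearson correlation is undefined")
    rd = r - r.mean()
    gd = g - g.mean()
    denom = np.sqrt((rd * rd).sum() * (gd * gd).sum())
    if denom == 0:
        return float("nan")
    return float((rd * gd).sum() / denom)


def manders(red, green, region: Optional[np.ndarray] = None,
            t_red: float = 0.0, t_green: float = 0.0) -> tuple[float, float]:
    """Mander's coefficients at the given thresholds.

    M1 = fraction of red intensity in pixels where green > t_green;
    M2 = fraction of green intensity in pixels where red > t_red.
    NaN is returned for a coefficient whose channel sum is zero.
    """
    r = _region_values(red, region)
    g = _region_values(green, region)
    r_sum = r.sum()
    g_sum = g.sum()
    m1 = float(r[g > t_green].sum() / r_sum) if r_sum > 0 else float("nan")
    m2 = float(g[r > t_red].sum() / g_sum) if g_sum > 0 else float("nan")
    return m1, m2


def costes_threshold(red, green, region: Optional[np.ndarray] = None,
                     step: float = 1.0) -> CostesFit:
    """Costes automatic threshold pair for Mander's coefficients.

    Fits green = a*red + b by ordinary least squares over the region, then
    scans t_red downward from max(red) in steps of ``step`` with
    t_green = a*t_red + b, and returns the highest t_red whose
    sub-threshold pixels (red < t_red AND green < t_green) have
    Pearson <= 0.  Where the sub-threshold correlation is undefined
    (fewer than two pixels, or a constant channel) the scan continues.

    When the fitted slope is not positive the procedure does not apply;
    per-channel Otsu thresholds are returned with a
    ``"costes_not_applicable"`` flag.
    """
    r = _region_values(red, region)
    g = _region_values(green, region)
    if r.size < 2:
        raise ValueError("Costes threshold needs at least 2 pixels")
    flags: list[str] = []
    if np.unique(r).size < 2 or np.unique(g).size < 2:
        raise ValueError("Costes threshold needs >= 2 distinct intensities per channel")

    a, b = np.polyfit(r, g, 1)
    if a <= 0:
        t_red = float(threshold_otsu(r.astype(np.float64)))
        t_green = float(threshold_otsu(g.astype(np.float64)))
        return CostesFit(slope=float(a), intercept=float(b),
                         t_red=t_red, t_green=t_green,
                         stop_pearson=float("nan"),
                         flags=("costes_not_applicable",))

    r_max, r_min = r.max(), r.min()
    last_t = r_min
    last_rho = float("nan")
    for t in np.arange(r_max, r_min - step / 2, -step):
        t_g = a * t + b
        below = (r < t) & (g < t_g)
        if below.sum() < 2:
            continue
        rb, gb = r[below], g[below]
        rd = rb - rb.mean()
        gd = gb - gb.mean()
        denom = np.sqrt((rd * rd).sum() * (gd * gd).sum())
        if denom == 0:
            continue
        rho = float((rd * gd).sum() / denom)
        last_t, last_rho = float(t), rho
        if rho <= 0:
            return CostesFit(slope=float(a), intercept=float(b),
                             t_red=float(t), t_green=float(a * t + b),
                             stop_pearson=rho, flags=tuple(flags))
    flags.append("scan_exhausted")
    return CostesFit(slope=float(a), intercept=float(b),
                     t_red=float(last_t), t_green=float(a * last_t + b),
                     stop_pearson=last_rho, flags=tuple(flags))


def coloc_per_cell(field: FieldOfView, mask: CellMask,
                   threshold_mode: str = "costes",
                   t_red: Optional[float] = None,
                   t_green: Optional[float] = None,
                   costes_step: float = 1.0) -> list[ColocResult]:
    """Per-cell Pearson and Mander's statistics.

    Pearson is always computed on raw (unthresholded) pixels; M1/M2 use
    thresholds chosen by ``threshold_mode``: ``"costes"`` (automatic, per
    cell), ``"fixed"`` (user-supplied ``t_red``/``t_green``), or
    ``"none"`` (zero thresholds, i.e. any nonzero intensity counts).
    Per-cell failures are flagged on that cell's result; other cells are
    unaffected.
    """
    if mask.shape != field.shape:
        raise ValueError(f"mask shape {mask.shape} != field shape {field.shape}")
    if threshold_mode not in ("costes", "fixed", "none"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    if threshold_mode == "fixed" and (t_red is None or t_green is None):
        raise ValueError("threshold_mode='fixed' requires t_red and t_green")

    red = field.red.data
    green = field.green.data
    results: list[ColocResult] = []
    for cell_id in mask.cell_ids():
        region = mask.labels == cell_id
        flags: list[str] = []
        r_val = pearson(red, green, region)
        if not np.isfinite(r_val):
            flags.append("pearson_undefined:constant_channel")

        if threshold_mode == "costes":
            try:
                fit = costes_threshold(red, green, region, step=costes_step)
                tr, tg = fit.t_red, fit.t_green
                flags.extend(fit.flags)
            except ValueError as exc:
                tr, tg = 0.0, 0.0
                flags.append(f"costes_failed:{exc}")
        elif threshold_mode == "fixed":
            tr, tg = float(t_red), float(t_green)
        else:
            tr, tg = 0.0, 0.0

        m1, m2 = manders(red, green, region, tr, tg)
        if not np.isfinite(m1):
            flags.append("m1_undefined:zero_red_sum")
        if not np.isfinite(m2):
            flags.append("m2_undefined:zero_green_sum")
        results.append(ColocResult(cell_id=int(cell_id), pearson_r=r_val,
                                   m1=m1, m2=m2, t_red=tr, t_green=tg,
                                   n_pixels=int(region.sum()),
                                   flags=tuple(flags)))
    return results
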