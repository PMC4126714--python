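"""Absolute qPCR quantification: standard curves and copies per cell.

A dilution series of standards with known template copy numbers yields a
linear standard curve Ct = slope * log10(copies) + intercept.  Amplification
efficiency derives from the slope as ``10**(-1/slope) - 1`` (1.0 means
perfect doubling each cycle, slope ≈ -3.32).

Copies per cell follow from the curve and the extraction bookkeeping: the
reaction uses a fixed RNA input (100 ng by convention), so the number of
cell-equivalents in a reaction is ``n_cells / total_rna_ng * 100`` — the
number of cells that produced 100 ng of RNA — and

    copies_per_cell = copies_in_reaction / cells_per_100ng.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "CopyEstimate",
    "fit_standard_curve",
    "ct_to_copies",
    "copies_to_ct",
    "copies_per_cell",
    "average_replicates",
    "copies_sd_from_ct_sd",
    "simulate_dilution_series",
    "RNA_INPUT_NG",
]

RNA_INPUT_NG = 100.0  # RNA template per reaction


@dataclass
class StandardCurve:
    """Fitted line Ct = slope * log10(copies) + intercept."""

    slope: float          # Ct per log10(copies); negative for a valid curve
    intercept: float      # Ct at 1 copy
    r_squared: float
    efficiency: float     # 10**(-1/slope) - 1; 1.0 == perfect doubling
    standards: tuple[tuple[float, float], ...]  # (copies, ct)

    @property
    def ct_range(self) -> tuple[float, float]:
        cts = [ct for _, ct in self.standards]
        return min(cts), max(cts)


@dataclass
class CopyEstimate:
    """Absolute transcript copies per cell, with the inputs echoed."""

    copies_in_reaction: float
    cells_per_100ng: float
    copies_per_cell: float
    ct: float
    n_cells: float
    total_rna_ng: float
    warnings: tuple[str, ...] = ()


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares standard curve from (copies, Ct) pairs.

    Requires at least three standards spanning two orders of magnitude,
    with Ct strictly decreasing as copies increase; a violating standard
    is named in the error.
    """
    pts = sorted((float(c), float(ct)) for c, ct in standards)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 standards, got {len(pts)}")
    copies = np.array([c for c, _ in pts])
    cts = np.array([ct for _, ct in pts])
    if np.any(copies <= 0):
        raise ValueError("standard copy numbers must be positive")
    if len(np.unique(copies)) != len(copies):
        dup = copies[:-1][np.diff(copies) == 0][0]
        raise ValueError(f"degenerate series: duplicate standard at {dup:g} copies")
    if np.log10(copies.max() / copies.min()) < 2:
        raise ValueError("standards must span at least 2 orders of magnitude")
    decreasing = np.diff(cts) < 0
    if not np.all(decreasing):
        bad = int(np.argmin(decreasing))
        raise ValueError(
            f"non-monotone series: Ct does not decrease from "
            f"{copies[bad]:g} to {copies[bad + 1]:g} copies"
        )

    fit = stats.linregress(np.log10(copies), cts)
    slope = float(fit.slope)
    if slope >= 0:
        raise ValueError(f"invalid curve: slope {slope:.3f} is not negative")
    return StandardCurve(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(10 ** (-1 / slope) - 1),
        standards=tuple((float(c), float(ct)) for c, ct in pts),
    )


def ct_to_copies(curve: StandardCurve, ct: float) -> float:
    """Template copies corresponding to a Ct value on the curve."""
    return float(10 ** ((ct - curve.intercept) / curve.slope))


def copies_to_ct(curve: StandardCurve, copies: float) -> float:
    """Ct value expected for a template copy number on the curve."""
    if copies <= 0:
        raise ValueError("copies must be positive")
    return float(curve.slope * math.log10(copies) + curve.intercept)


def copies_per_cell(curve: StandardCurve, ct: float, n_cells: float,
                    total_rna_ng: float,
                    rna_input_ng: float = RNA_INPUT_NG) -> CopyEstimate:
    """Estimate transcript copies per cell from a sample Ct.

    ``n_cells`` and ``total_rna_ng`` are the extraction counts: how many
    cells yielded how much total RNA.  A Ct outside the calibrated range
    of the standards is extrapolated, with a warning recorded.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if total_rna_ng <= 0:
        raise ValueError("total_rna_ng must be positive")
    warnings: list[str] = []
    lo, hi = curve.ct_range
    if not (lo <= ct <= hi):
        warnings.append(
            f"extrapolation: Ct {ct:.2f} outside calibrated range [{lo:.2f}, {hi:.2f}]"
        )
    copies_rxn = ct_to_copies(curve, ct)
    cells_eq = n_cells / total_rna_ng * rna_input_ng
    return CopyEstimate(
        copies_in_reaction=copies_rxn,
        cells_per_100ng=cells_eq,
        copies_per_cell=copies_rxn / cells_eq,
        ct=float(ct), n_cells=float(n_cells),
        total_rna_ng=float(total_rna_ng),
        warnings=tuple(warnings),
    )


def average_replicates(samples: pd.DataFrame) -> pd.DataFrame:
    """Average replicate Ct values per (sample, target).

    Expects columns ``sample``, ``target``, ``ct`` (and optionally
    ``replicate``).  Returns one row per group with ``ct_mean``,
    ``ct_sd`` (sample SD; 0 for a single replicate) and ``n_replicates``.
    The copy-number SD implied by a Ct SD on a curve with slope *a*
    follows the first-order delta method:
    ``sd_copies = |copies * ln(10) / a| * sd_ct`` — apply it after
    converting ``ct_mean`` with :func:`ct_to_copies`.
    """
    required = {"sample", "target", "ct"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table missing columns: {sorted(missing)}")
    grouped = samples.groupby(["sample", "target"], as_index=False).agg(
        ct_mean=("ct", "mean"),
        ct_sd=("ct", lambda x: float(x.std(ddof=1)) if len(x) > 1 else 0.0),
        n_replicates=("ct", "size"),
    )
    return grouped


def copies_sd_from_ct_sd(curve: StandardCurve, copies: float, ct_sd: float) -> float:
    """First-order (delta-method) SD of copies implied by a Ct SD."""
    return abs(copies * math.log(10) / curve.slope) * ct_sd


def simulate_dilution_series(slope: float = -1 / math.log10(2),
                             intercept: float = 40.0,
                             copies: Sequence[float] = (1e3, 1e4, 1e5, 1e6, 1e7),
                             ct_sd: float = 0.0,
                             rng: np.random.Generator | None = None
                             ) -> list[tuple[float, float]]:
    """Generate a (copies, Ct) dilution series from a true line, with
    optional Gaussian Ct noise — for validation and worked examples."""
    if ct_sd > 0 and rng is None:
        rng = np.random.default_rng()
    out = []
    for c in copies:
        ct = slope * math.log10(c) + intercept
        if ct_sd > 0:
            ct += float(rng.normal(0, ct_sd))
        out.append((float(c), float(ct)))
    return out
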