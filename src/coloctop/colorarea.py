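"""Three-colour relative-area classification of a two-channel field.

Pixels are partitioned into three *disjoint* classes, in sequence:

1. the red and green channels are combined with an AND operation and
   thresholded — pixels carrying both signals are "yellow";
2. yellow pixels are removed from the red channel, which is then
   thresholded — the surviving pixels are "red";
3. yellow and red pixels are removed from the green channel, which is
   then thresholded — the remainder is "green".

A pixel classified yellow can therefore never also count as red or
green.  Relative areas are reported as fractions of the classified union
(the three fractions sum to 1 whenever any pixel is classified).

Two AND semantics are provided: ``"intersection"`` (binarize each
channel at its threshold, intersect the masks — the default) and
``"minimum"`` (pixelwise minimum of the grayscale channels, thresholded
as an image).  Thresholds default to Otsu's method per image and are
echoed into the result for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .simulate import FieldOfView

__all__ = ["ColorAreaResult", "classify_colors", "aggregate_fields"]


@dataclass
class ColorAreaResult:
    """Relative colour areas of one field of view."""

    yellow_frac: float
    red_frac: float
    green_frac: float
    yellow_px: int
    red_px: int
    green_px: int
    t_and: float
    t_red: float
    t_green: float
    field_id: str = "field"
    flags: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return "no_signal" not in self.flags


def _otsu_or(value: Optional[float], img: np.ndarray) -> float:
    if value is not None:
        return float(value)
    if np.unique(img).size < 2:
        return float(img.max())  # constant image: nothing above threshold
    return float(threshold_otsu(img.astype(np.float64)))


def classify_colors(field: FieldOfView,
                    threshold_and: Optional[float] = None,
                    threshold_red: Optional[float] = None,
                    threshold_green: Optional[float] = None,
                    mode: str = "intersection") -> ColorAreaResult:
    """Classify pixels as yellow / red / green and compute relative areas.

    Thresholds are strict (``intensity > t``); ``None`` selects Otsu's
    threshold on the image the step examines.  ``threshold_and`` only
    applies in ``mode="minimum"``.
    """
    if mode not in ("intersection", "minimum"):
        raise ValueError(f"unknown AND mode {mode!r}")
    red = field.red.data.astype(float)
    green = field.green.data.astype(float)

    t_red = _otsu_or(threshold_red, red)
    t_green = _otsu_or(threshold_green, green)

    if mode == "intersection":
        yellow = (red > t_red) & (green > t_green)
        t_and = float("nan")
    else:
        and_img = np.minimum(red, green)
        t_and = _otsu_or(threshold_and, and_img)
        yellow = and_img > t_and

    # step 2: remove yellow from red, threshold the remainder
    red_work = red.copy()
    red_work[yellow] = 0
    red_set = red_work > t_red

    # step 3: remove yellow and red from green, threshold the remainder
    green_work = green.copy()
    green_work[yellow | red_set] = 0
    green_set = green_work > t_green

    y, r, g = int(yellow.sum()), int(red_set.sum()), int(green_set.sum())
    total = y + r + g
    if total == 0:
        return ColorAreaResult(
            yellow_frac=float("nan"), red_frac=float("nan"),
            green_frac=float("nan"), yellow_px=0, red_px=0, green_px=0,
            t_and=t_and, t_red=t_red, t_green=t_green,
            field_id=field.field_id, flags=("no_signal",),
        )
    return ColorAreaResult(
        yellow_frac=y / total, red_frac=r / total, green_frac=g / total,
        yellow_px=y, red_px=r, green_px=g,
        t_and=t_and, t_red=t_red, t_green=t_green,
        field_id=field.field_id,
    )


def aggregate_fields(results: Sequence[ColorAreaResult]) -> pd.DataFrame:
    """Mean and sample SD of each colour fraction across fields of view.

    Averaging is at the field level (one fraction triple per field), not
    pixel-pooled.  Fields flagged ``no_signal`` are excluded; with a
    single contributing field the SD is reported as 0 and flagged.
    """
    defined = [r for r in results if r.defined]
    if not defined:
        raise ValueError("no defined colour-area results to aggregate")
    n = len(defined)
    rows = []
    for colour, attr in (("yellow", "yellow_frac"), ("red", "red_frac"),
                         ("green", "green_frac")):
        vals = np.array([getattr(r, attr) for r in defined])
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append({
            "colour": colour,
            "mean_frac": float(vals.mean()),
            "sd_frac": sd,
            "n_fields": n,
            "n_excluded": len(results) - n,
            "flags": "single_field" if n == 1 else "",
        })
    return pd.DataFrame(rows)
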