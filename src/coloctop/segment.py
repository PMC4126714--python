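"""Per-cell segmentation: label masks for per-cell colocalization statistics.

The default pipeline thresholds the red+green sum image with Otsu's method
and separates touching cells by watershed, seeded from the nuclei channel
when one is present and from distance-transform maxima otherwise.
Watershed line pixels are assigned to background so that per-cell sums
never double-count a pixel.  A user-supplied label mask can be validated
and passed through instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.feature import peak_local_max
from skimage.morphology import disk
from skimage.segmentation import watershed

from .simulate import FieldOfView

__all__ = ["CellMask", "segment_cells"]


@dataclass
class CellMask:
    """Integer label raster: 0 = background, k > 0 = cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("cell mask must be a 2D label raster")
        if np.issubdtype(self.labels.dtype, np.floating):
            raise ValueError("cell mask must be an integer raster")
        if self.labels.min() < 0:
            raise ValueError("cell mask labels must be nonnegative")

    @property
    def n_cells(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cell_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])


def _auto_segment(field: FieldOfView, min_area: int) -> CellMask:
    total = field.red.data.astype(float) + field.green.data.astype(float)
    smooth = gaussian(total, sigma=2, preserve_range=True)
    thr = threshold_otsu(smooth)
    spots = smooth > thr

    nuc_mask = None
    if field.nuclei is not None:
        nuc = gaussian(field.nuclei.data.astype(float), sigma=2, preserve_range=True)
        nuc_mask = nuc > threshold_otsu(nuc)

    # punctate stains cover a cell sparsely: close small gaps between
    # structures (and bridge through the nucleus) to recover a footprint
    fg = spots if nuc_mask is None else (spots | nuc_mask)
    fg = ndimage.binary_closing(fg, structure=disk(6))
    fg = ndimage.binary_fill_holes(fg)

    if nuc_mask is not None:
        markers = cc_label(nuc_mask)
    else:
        dist = ndimage.distance_transform_edt(fg)
        peaks = peak_local_max(dist, min_distance=10, labels=fg, exclude_border=False)
        markers = np.zeros(fg.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i

    if markers.max() == 0:
        raise ValueError(
            f"no cells found: no watershed seeds above threshold {thr:.2f}"
        )

    dist = ndimage.distance_transform_edt(fg)
    labels = watershed(-dist, markers=markers, mask=fg, watershed_line=True)

    # drop undersized regions, then relabel sequentially
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for region in regionprops(labels):
        if region.area >= min_area:
            out[labels == region.label] = next_id
            next_id += 1
    if next_id == 1:
        raise ValueError(
            f"no cells found: no region of at least {min_area} px above "
            f"threshold {thr:.2f}"
        )
    return CellMask(labels=out)


def segment_cells(field: FieldOfView, method: str = "threshold_watershed",
                  min_area: int = 64,
                  provided: Optional[CellMask] = None) -> CellMask:
    """Segment a field into per-cell labels.

    Parameters
    ----------
    field
        The two/three-channel field of view.
    method
        ``"threshold_watershed"`` (Otsu on red+green, nuclei- or
        distance-seeded watershed) or ``"provided_mask"`` (validate and
        pass through ``provided``).
    min_area
        Minimum retained region area in pixels.
    provided
        User-supplied mask for ``method="provided_mask"``.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if method == "provided_mask":
        if provided is None:
            raise ValueError("method='provided_mask' requires a mask")
        if provided.shape != field.shape:
            raise ValueError(
                f"provided mask shape {provided.shape} does not match "
                f"field shape {field.shape}"
            )
        return provided
    if method != "threshold_watershed":
        raise ValueError(f"unknown segmentation method {method!r}")
    if not np.any(field.red.data) and not np.any(field.green.data):
        raise ValueError("no cells found: both channels are empty (threshold n/a)")
    return _auto_segment(field, min_area)
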