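"""Synthetic two-channel fluorescence micrographs with known ground truth.

The simulator emulates immunofluorescence co-staining of a single protein
species with two antibodies: a "red" channel (N-terminal antibody) that
labels every structure, and a "green" channel (C-terminal epitope tag)
that labels a controllable fraction of the red signal.  Three staining
phenotypes are supported, mirroring the distinct subcellular distributions
of the IFITM protein family:

``membrane_ring``
    a thin annulus at the cell edge (plasma-membrane staining),
``dispersed_punctae``
    small disks scattered through the cytoplasm (dispersed vesicles),
``perinuclear_cluster``
    small disks packed tightly against the nucleus (perinuclear
    endosomal cluster).

Two biological dials drive the downstream statistics:

``true_overlap``
    the intensity-weighted fraction of red signal that also carries green
    signal, assigned at the level of whole structures (one structure per
    cell may be split to hit the requested fraction exactly);
``green_loss``
    the fraction of structures whose green signal is removed entirely,
    modelling proteolytic loss of the C-terminal tag in acidified
    compartments.

Image degradation follows the usual forward model: Gaussian PSF blur,
constant background, Poisson shot noise, Gaussian read noise, and
quantization to the requested bit depth — in that order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

PHENOTYPES = ("membrane_ring", "dispersed_punctae", "perinuclear_cluster")

__all__ = [
    "PHENOTYPES",
    "SimParams",
    "ChannelImage",
    "FieldOfView",
    "CellTruth",
    "GroundTruth",
    "simulate_field",
    "write_field",
    "realized_overlap",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated field of view.

    Intensities are in detector units (ADU).  ``photon_scale`` is the
    ADU-per-photon gain used for shot noise: expected photon count per
    pixel is ``intensity / photon_scale``, so larger values mean noisier
    images; 0 disables shot noise.  ``amplitude`` is the signal level of
    a structure pixel before blur and noise.
    """

    phenotype: str = "dispersed_punctae"
    n_cells: int = 5
    image_shape: tuple[int, int] = (512, 512)
    true_overlap: float = 0.6
    green_loss: float = 0.0
    psf_sigma: float = 1.2
    background_level: float = 100.0
    photon_scale: float = 4.0
    read_noise_sd: float = 3.0
    bit_depth: int = 16
    seed: int = 0
    cell_radius: int = 40
    nucleus_radius: int = 12
    n_structures: int = 18
    structure_min_sep: float = 8.0
    amplitude: float = 1200.0
    include_nuclei: bool = True

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"unknown phenotype {self.phenotype!r}; expected one of {PHENOTYPES}"
            )
        if not (0.0 <= self.true_overlap <= 1.0):
            raise ValueError(f"true_overlap must be in [0, 1], got {self.true_overlap}")
        if not (0.0 <= self.green_loss <= 1.0):
            raise ValueError(f"green_loss must be in [0, 1], got {self.green_loss}")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass
class ChannelImage:
    """A single-channel 2D intensity raster with bit-depth metadata."""

    data: np.ndarray
    bit_depth: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError(f"channel {self.name!r} must be 2D, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class FieldOfView:
    """Paired red/green channels (plus optional nuclei) from one acquisition."""

    red: ChannelImage
    green: ChannelImage
    nuclei: Optional[ChannelImage] = None
    pixel_size: Optional[float] = None  # µm per pixel, metadata only
    field_id: str = "field"

    def __post_init__(self) -> None:
        channels = [self.red, self.green] + ([self.nuclei] if self.nuclei is not None else [])
        shapes = {c.shape for c in channels}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        depths = {c.bit_depth for c in channels}
        if len(depths) != 1:
            raise ValueError(f"channel bit depths differ: {sorted(depths)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass
class CellTruth:
    """Ground-truth record for one simulated cell."""

    cell_id: int
    phenotype: str
    realized_overlap: float
    n_structures: int
    centroid: tuple[float, float]  # (row, col)


@dataclass
class GroundTruth:
    """Simulator-side truth: per-cell records plus the noiseless rasters.

    ``red_clean``/``green_clean`` are the integer-valued signal rasters
    before PSF, background and noise; every realized overlap is
    recomputable from them (see :func:`realized_overlap`).
    """

    params: SimParams
    cells: list[CellTruth]
    red_clean: np.ndarray = field(repr=False)
    green_clean: np.ndarray = field(repr=False)


def realized_overlap(red_clean: np.ndarray, green_clean: np.ndarray,
                     region: np.ndarray) -> float:
    """Intensity-weighted fraction of red signal co-located with green.

    Computed on noiseless rasters over a boolean pixel region; NaN when
    the region carries no red signal.
    """
    r = np.asarray(red_clean, dtype=float)[region]
    g = np.asarray(green_clean, dtype=float)[region]
    total = r.sum()
    if total == 0:
        return float("nan")
    return float(r[g > 0].sum() / total)


# ---------------------------------------------------------------------------
# geometry helpers


def _disk_coords(center: tuple[float, float], radius: float,
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    r0 = max(int(np.floor(center[0] - radius)), 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 1, shape[0])
    c0 = max(int(np.floor(center[1] - radius)), 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    keep = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return rr[keep], cc[keep]


def _place_cells(params: SimParams, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Sample non-overlapping cell centers; explicit error when the field
    cannot hold the requested number of cells."""
    shape = params.image_shape
    R = params.cell_radius
    margin = R + 2
    if shape[0] < 2 * margin or shape[1] < 2 * margin:
        raise ValueError(
            f"image {shape} too small for cells of radius {R} "
            f"(needs at least {2 * margin} pixels per side)"
        )
    min_sep = 2 * R + 4
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 5000 * params.n_cells
    while len(centers) < params.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"image {shape} too small to place {params.n_cells} "
                f"non-overlapping cells of radius {R} "
                f"(placed {len(centers)} after {max_attempts} attempts)"
            )
        cand = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        )
        if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= min_sep**2 for c in centers):
            centers.append(cand)
    return centers


def _cell_structures(params: SimParams, center: tuple[float, float],
                     nucleus_center: tuple[float, float],
                     rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pixel coordinate lists for each structure of one cell.

    Structures within a cell are kept disjoint (first writer wins) so that
    structure-level green assignment and green loss are unambiguous.
    """
    shape = params.image_shape
    R = params.cell_radius
    claimed = set()

    def claim(rr: np.ndarray, cc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        keep_r, keep_c = [], []
        for r, c in zip(rr.tolist(), cc.tolist()):
            if (r, c) not in claimed:
                claimed.add((r, c))
                keep_r.append(r)
                keep_c.append(c)
        return np.array(keep_r, dtype=int), np.array(keep_c, dtype=int)

    structures: list[tuple[np.ndarray, np.ndarray]] = []

    if params.phenotype == "membrane_ring":
        rr, cc = _disk_coords(center, R, shape)
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        ring = d2 > (R - 3) ** 2
        rr, cc = rr[ring], cc[ring]
        # partition the ring into angular arc segments ("structures")
        ang = np.arctan2(rr - center[0], cc - center[1])
        bins = np.floor((ang + np.pi) / (2 * np.pi) * params.n_structures).astype(int)
        bins = np.clip(bins, 0, params.n_structures - 1)
        for b in range(params.n_structures):
            sel = bins == b
            if sel.any():
                structures.append(claim(rr[sel], cc[sel]))
    else:
        placed_centers: list[tuple[float, float]] = []
        for _ in range(params.n_structures):
            radius = int(rng.integers(1, 4))
            for _try in range(200):
                if params.phenotype == "dispersed_punctae":
                    ang = rng.uniform(0, 2 * np.pi)
                    dist = np.sqrt(rng.uniform(0, 1)) * (R - 4)
                    cand = (center[0] + dist * np.sin(ang), center[1] + dist * np.cos(ang))
                    dn = np.hypot(cand[0] - nucleus_center[0], cand[1] - nucleus_center[1])
                    if dn <= params.nucleus_radius + radius:
                        continue  # keep punctae cytoplasmic
                    # dispersed vesicles are optically resolvable structures
                    if any(np.hypot(cand[0] - p[0], cand[1] - p[1])
                           < params.structure_min_sep for p in placed_centers):
                        continue
                else:  # perinuclear_cluster: hug the nucleus, tightly packed
                    ang = rng.uniform(0, 2 * np.pi)
                    dist = params.nucleus_radius + 1 + radius + rng.exponential(2.5)
                    cand = (
                        nucleus_center[0] + dist * np.sin(ang),
                        nucleus_center[1] + dist * np.cos(ang),
                    )
                dc = np.hypot(cand[0] - center[0], cand[1] - center[1])
                if dc <= R - 2 - radius:
                    break
            else:
                continue  # could not place this puncta; skip it
            placed_centers.append(cand)
            rr, cc = _disk_coords(cand, radius, shape)
            rr, cc = claim(rr, cc)
            if rr.size:
                structures.append((rr, cc))
    return structures


# ---------------------------------------------------------------------------
# green assignment


def _assign_green(structures: Sequence[tuple[np.ndarray, np.ndarray]],
                  amplitude: float, true_overlap: float,
                  rng: np.random.Generator):
    """Choose green-positive pixels so the intensity-weighted overlap of the
    cell equals ``true_overlap`` as closely as quantization allows.

    All structure pixels start at a common integer red amplitude A.  Green
    is assigned at the level of whole structures (greedy over a shuffled
    order); the residue is absorbed by partially greening the *smallest*
    remaining structure, inside which one "split" pixel has its red
    amplitude adjusted so the red-weighted green fraction lands on the
    target exactly.  Confining the partial assignment to the smallest
    structure keeps the sub-structure mixing introduced by later PSF blur
    down to a few pixels per cell.  The adjusted amplitude is rounded to
    keep the raster integer-valued; for amplitudes divisible by the overlap
    fraction's reduced denominator the result is still exact.

    Returns per-pixel (values, green) arrays aligned with the structures'
    concatenated pixel order.
    """
    A = float(round(amplitude))
    f = true_overlap
    sizes = [s[0].size for s in structures]
    n = int(sum(sizes))
    offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    vals = np.full(n, A)
    green = np.zeros(n, dtype=bool)
    if n == 0 or f <= 0.0:
        return vals, green
    if f >= 1.0:
        green[:] = True
        return vals, green

    # exact-overlap bookkeeping: k full-amplitude green pixels plus one
    # split pixel with adjusted red amplitude
    t = f * (n - 1)
    k1 = int(np.floor(t + 1e-12))
    frac = t - k1
    if frac <= (1.0 - f) + 1e-12:
        k = k1
        split_val = A * frac / (1.0 - f)
        split_green = True
    else:
        k = k1 + 1
        split_val = A * (k / f - (n - 1))
        split_green = False
    split_val = float(np.clip(round(split_val), 0, round(A)))
    if k >= n:  # degenerate guard (f very close to 1)
        green[:] = True
        return vals, green

    # greedy whole-structure assignment over a shuffled order
    order = list(range(len(structures)))
    rng.shuffle(order)
    budget = k
    nongreen: list[int] = []
    for i in order:
        if sizes[i] <= budget:
            green[offsets[i]:offsets[i] + sizes[i]] = True
            budget -= sizes[i]
        else:
            nongreen.append(i)

    if budget > 0 or frac > 1e-12:
        # partial structure: smallest one still available (every skipped
        # structure has more pixels than the remaining budget)
        partial = min(nongreen, key=lambda i: sizes[i])
        start = offsets[partial]
        green[start:start + budget] = True
        vals[start + budget] = split_val
        green[start + budget] = split_green and split_val > 0
    return vals, green


def _build_cell_signal(params: SimParams,
                       structures: Sequence[tuple[np.ndarray, np.ndarray]],
                       red: np.ndarray, green: np.ndarray,
                       rng: np.random.Generator) -> int:
    """Paint one cell's structures into the clean rasters; returns the
    number of structures actually drawn."""
    A = float(round(params.amplitude))
    vals, green_mask = _assign_green(structures, A, params.true_overlap, rng)
    flat_r = (np.concatenate([s[0] for s in structures])
              if structures else np.array([], int))
    flat_c = (np.concatenate([s[1] for s in structures])
              if structures else np.array([], int))

    red[flat_r, flat_c] = vals
    green[flat_r, flat_c] = np.where(green_mask, vals, 0.0)

    # structure-level green loss: remove the tag signal from whole structures
    n_struct = len(structures)
    n_lost = int(round(params.green_loss * n_struct))
    if n_lost > 0:
        lost = rng.choice(n_struct, size=n_lost, replace=False)
        for i in lost:
            rr, cc = structures[i]
            green[rr, cc] = 0.0
    return n_struct


# ---------------------------------------------------------------------------
# forward imaging model


def _degrade(clean: np.ndarray, params: SimParams,
             rng: np.random.Generator) -> np.ndarray:
    """PSF blur -> background -> Poisson shot noise -> Gaussian read noise
    -> quantization.  The order is fixed and part of the model contract."""
    img = clean.astype(float)
    if params.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, params.psf_sigma)
    img = img + params.background_level
    if params.photon_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) / params.photon_scale) * params.photon_scale
    if params.read_noise_sd > 0:
        img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
    vmax = 2**params.bit_depth - 1
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    return np.clip(np.round(img), 0, vmax).astype(dtype)


def simulate_field(params: SimParams):
    """Generate one annotated field of view.

    Returns ``(field, mask, truth)`` where ``field`` is the degraded
    :class:`FieldOfView`, ``mask`` the true per-cell label raster
    (:class:`~coloctop.segment.CellMask`), and ``truth`` the
    :class:`GroundTruth` with per-cell realized overlaps computed from the
    noiseless rasters after green loss.
    """
    from .segment import CellMask  # local import to avoid a cycle

    rng = np.random.default_rng(params.seed)
    shape = params.image_shape
    centers = _place_cells(params, rng)

    red_clean = np.zeros(shape, dtype=float)
    green_clean = np.zeros(shape, dtype=float)
    nuclei_clean = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    cells: list[CellTruth] = []

    for k, center in enumerate(centers, start=1):
        off = rng.uniform(-params.cell_radius / 4, params.cell_radius / 4, size=2)
        nucleus_center = (center[0] + off[0], center[1] + off[1])
        rr, cc = _disk_coords(center, params.cell_radius, shape)
        labels[rr, cc] = k
        nr, nc = _disk_coords(nucleus_center, params.nucleus_radius, shape)
        nuclei_clean[nr, nc] = 0.7 * round(params.amplitude)

        structures = _cell_structures(params, center, nucleus_center, rng)
        n_struct = _build_cell_signal(params, structures, red_clean, green_clean, rng)
        region = labels == k
        cells.append(
            CellTruth(
                cell_id=k,
                phenotype=params.phenotype,
                realized_overlap=realized_overlap(red_clean, green_clean, region),
                n_structures=n_struct,
                centroid=(float(center[0]), float(center[1])),
            )
        )

    red = ChannelImage(_degrade(red_clean, params, rng), params.bit_depth, "red")
    green = ChannelImage(_degrade(green_clean, params, rng), params.bit_depth, "green")
    nuclei = None
    if params.include_nuclei:
        nuclei = ChannelImage(_degrade(nuclei_clean, params, rng), params.bit_depth, "nuclei")

    field = FieldOfView(red=red, green=green, nuclei=nuclei,
                        field_id=f"sim_{params.phenotype}_{params.seed}")
    mask = CellMask(labels=labels)
    truth = GroundTruth(params=params, cells=cells,
                        red_clean=red_clean, green_clean=green_clean)
    return field, mask, truth


def write_field(field: FieldOfView, mask, truth: Optional[GroundTruth],
                directory) -> dict:
    """Write a simulated field to ``directory``; see :mod:`coloctop.io`."""
    from . import io as _io

    return _io.write_field(field, mask, truth, directory)
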