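"""TIFF and sidecar I/O for fields, masks and ground truth.

Channels are written as one multi-page grayscale TIFF per field with a
documented page order — page 0 red, page 1 green, page 2 nuclei (when
present) — or can be read from one single-page TIFF per channel.  Label
masks are 16-bit TIFFs.  Ground truth travels as a JSON sidecar holding
the simulation parameters and the per-cell records (not the rasters).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .segment import CellMask
from .simulate import (CellTruth, ChannelImage, FieldOfView, GroundTruth,
                       SimParams)

__all__ = ["write_field", "read_field", "read_mask", "write_mask",
           "read_truth_sidecar", "PAGE_ORDER"]

PAGE_ORDER = ("red", "green", "nuclei")


def write_field(field: FieldOfView, mask: Optional[CellMask] = None,
                truth: Optional[GroundTruth] = None,
                directory: str | Path = ".") -> dict[str, Path]:
    """Write a field (and optionally its mask and ground truth) to disk.

    Returns a dict of the paths written: ``channels`` (multi-page TIFF in
    the order red, green[, nuclei]), ``mask``, ``truth``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pages = [field.red.data, field.green.data]
    if field.nuclei is not None:
        pages.append(field.nuclei.data)
    channels_path = directory / f"{field.field_id}_channels.tif"
    try:
        tifffile.imwrite(channels_path, np.stack(pages),
                         photometric="minisblack", planarconfig="separate")
    except OSError as exc:
        raise OSError(f"failed to write {channels_path}: {exc}") from exc
    paths["channels"] = channels_path

    if mask is not None:
        paths["mask"] = write_mask(mask, directory / f"{field.field_id}_mask.tif")

    if truth is not None:
        truth_path = directory / f"{field.field_id}_truth.json"
        payload = {
            "params": dataclasses.asdict(truth.params),
            "cells": [dataclasses.asdict(c) for c in truth.cells],
        }
        truth_path.write_text(json.dumps(payload, indent=2))
        paths["truth"] = truth_path
    return paths


def write_mask(mask: CellMask, path: str | Path) -> Path:
    path = Path(path)
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError(f"too many labels for a 16-bit mask: {mask.labels.max()}")
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    return path


def _read_tiff(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        return tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / not a TIFF
        raise OSError(f"failed to read TIFF {path}: {exc}") from exc


def _bit_depth(arr: np.ndarray, path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16")


def read_field(channels: Optional[str | Path] = None,
               red: Optional[str | Path] = None,
               green: Optional[str | Path] = None,
               nuclei: Optional[str | Path] = None,
               field_id: Optional[str] = None,
               pixel_size: Optional[float] = None) -> FieldOfView:
    """Read a field either from a multi-page TIFF (``channels``; page
    order red, green[, nuclei]) or from per-channel TIFFs.  Channel shapes
    and bit depths are validated and mismatches named per file."""
    if channels is not None:
        stack = _read_tiff(channels)
        if stack.ndim == 2:
            raise ValueError(f"{channels}: expected >= 2 pages (red, green), got a single page")
        if stack.shape[0] < 2:
            raise ValueError(f"{channels}: expected >= 2 pages (red, green), got {stack.shape[0]}")
        depth = _bit_depth(stack, channels)
        name = field_id or Path(channels).stem.replace("_channels", "")
        imgs = [ChannelImage(stack[i], depth, PAGE_ORDER[i])
                for i in range(min(stack.shape[0], 3))]
        nuc = imgs[2] if len(imgs) > 2 else None
        return FieldOfView(red=imgs[0], green=imgs[1], nuclei=nuc,
                           pixel_size=pixel_size, field_id=name)

    if red is None or green is None:
        raise ValueError("provide either `channels` or both `red` and `green` paths")
    arrays = {"red": _read_tiff(red), "green": _read_tiff(green)}
    paths = {"red": red, "green": green}
    if nuclei is not None:
        arrays["nuclei"] = _read_tiff(nuclei)
        paths["nuclei"] = nuclei
    depths = {n: _bit_depth(a, paths[n]) for n, a in arrays.items()}
    shapes = {n: a.shape for n, a in arrays.items()}
    if len(set(shapes.values())) != 1:
        detail = ", ".join(f"{paths[n]}: {s}" for n, s in shapes.items())
        raise ValueError(f"channel shapes differ ({detail})")
    if len(set(depths.values())) != 1:
        detail = ", ".join(f"{paths[n]}: {d}-bit" for n, d in depths.items())
        raise ValueError(f"channel bit depths differ ({detail})")
    depth = depths["red"]
    return FieldOfView(
        red=ChannelImage(arrays["red"], depth, "red"),
        green=ChannelImage(arrays["green"], depth, "green"),
        nuclei=ChannelImage(arrays["nuclei"], depth, "nuclei") if nuclei is not None else None,
        pixel_size=pixel_size,
        field_id=field_id or Path(red).stem,
    )


def read_mask(path: str | Path) -> CellMask:
    arr = _read_tiff(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label mask must be an integer TIFF, got {arr.dtype}")
    return CellMask(labels=arr.astype(np.int32))


def read_truth_sidecar(path: str | Path) -> tuple[SimParams, list[CellTruth]]:
    """Reparse a ground-truth JSON sidecar into SimParams and cell records."""
    payload = json.loads(Path(path).read_text())
    pdict = dict(payload["params"])
    pdict["image_shape"] = tuple(pdict["image_shape"])
    params = SimParams(**pdict)
    cells = [CellTruth(**{**c, "centroid": tuple(c["centroid"])})
             for c in payload["cells"]]
    return params, cells
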