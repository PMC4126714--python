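"""Summary tables and the end-to-end pipeline.

``summarize`` condenses per-cell colocalization results into the standard
report layout — number of cells, Pearson's R, Mander's M1 and M2, each as
mean ± SD per group — and ``run_pipeline`` wires the stages together:
simulate (or read) fields, segment cells, compute per-cell colocalization
and per-field colour areas, and write per-cell CSVs alongside the summary
so every table is exactly recomputable from the rows it ships with.

SDs are sample standard deviations (ddof=1) throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .colorarea import ColorAreaResult, aggregate_fields, classify_colors
from .metrics import ColocResult, coloc_per_cell
from .segment import segment_cells
from .simulate import SimParams, simulate_field

__all__ = ["RunConfig", "summarize", "coloc_results_to_frame", "run_pipeline"]

logger = logging.getLogger("coloctop")


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    sim: Optional[SimParams] = None          # simulate when set ...
    input_fields: tuple[tuple[str, ...], ...] = ()  # ... else read these TIFF paths
    n_fields: int = 5
    condition: str = "condition"
    segmentation: str = "truth"              # "truth" | "auto"
    min_area: int = 64
    threshold_mode: str = "costes"           # "costes" | "fixed" | "none"
    t_red: Optional[float] = None
    t_green: Optional[float] = None
    colorarea_t_red: Optional[float] = None
    colorarea_t_green: Optional[float] = None
    out_dir: str = "coloctop_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if d.get("sim") is not None:
            sim = dict(d["sim"])
            sim["image_shape"] = tuple(sim["image_shape"])
            d["sim"] = SimParams(**sim)
        d["input_fields"] = tuple(tuple(f) for f in d.get("input_fields", ()))
        return cls(**d)


def coloc_results_to_frame(results: Sequence[ColocResult],
                           condition: str = "",
                           field_id: str = "") -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(rows)
    if len(df):
        df["flags"] = df["flags"].map(lambda f: ";".join(f))
        df.insert(0, "condition", condition)
        df.insert(1, "field_id", field_id)
    return df


def summarize(per_cell: pd.DataFrame, group_by: str = "condition") -> pd.DataFrame:
    """Per-group summary of per-cell colocalization results.

    One row per group: cell count, mean ± SD of Pearson's R, M1 and M2.
    Cells whose metric is undefined (NaN) are excluded metric-wise and
    counted in the ``n_excluded_*`` columns.
    """
    if per_cell.empty:
        raise ValueError("no per-cell results to summarize")
    rows = []
    for group, sub in per_cell.groupby(group_by):
        row: dict = {group_by: group, "n_cells": len(sub)}
        for metric, label in (("pearson_r", "pearson_r"), ("m1", "m1"), ("m2", "m2")):
            vals = sub[metric].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            n_excl = int((~ok).sum())
            if n_excl:
                logger.info("group %s: excluding %d cells with undefined %s",
                            group, n_excl, label)
            defined = vals[ok]
            row[f"{label}_mean"] = float(defined.mean()) if defined.size else float("nan")
            row[f"{label}_sd"] = (float(defined.std(ddof=1)) if defined.size > 1 else 0.0)
            row[f"n_excluded_{label}"] = n_excl
        rows.append(row)
    return pd.DataFrame(rows)


def _field_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate-or-read -> segment -> metrics + colour areas -> summary.

    Writes, under ``config.out_dir``: the echoed config, per-cell
    colocalization CSV, per-field colour-area CSV, and the two summary
    CSVs.  Returns the tables and paths.  Identical configs (including
    seed) produce identical outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    fields = []
    if config.sim is not None:
        seeds = _field_seeds(config.seed, config.n_fields)
        for i, s in enumerate(seeds):
            params = replace(config.sim, seed=s)
            logger.info("simulating field %d/%d (seed %d)", i + 1, config.n_fields, s)
            fov, mask, truth = simulate_field(params)
            fov = dataclasses.replace(fov, field_id=f"{config.condition}_f{i:02d}")
            fields.append((fov, mask, truth))
    elif config.input_fields:
        for i, paths in enumerate(config.input_fields):
            try:
                if len(paths) == 1:
                    fov = _io.read_field(channels=paths[0])
                else:
                    fov = _io.read_field(red=paths[0], green=paths[1],
                                         nuclei=paths[2] if len(paths) > 2 else None)
            except Exception as exc:
                raise RuntimeError(f"input stage failed for field {i}: {exc}") from exc
            fields.append((fov, None, None))
    else:
        raise ValueError("RunConfig needs either `sim` params or `input_fields`")

    per_cell_frames = []
    area_results: list[ColorAreaResult] = []
    for fov, true_mask, _truth in fields:
        try:
            if config.segmentation == "truth" and true_mask is not None:
                mask = true_mask
            else:
                mask = segment_cells(fov, min_area=config.min_area)
        except Exception as exc:
            raise RuntimeError(f"segmentation stage failed on {fov.field_id}: {exc}") from exc
        try:
            results = coloc_per_cell(fov, mask, threshold_mode=config.threshold_mode,
                                     t_red=config.t_red, t_green=config.t_green)
        except Exception as exc:
            raise RuntimeError(f"metrics stage failed on {fov.field_id}: {exc}") from exc
        per_cell_frames.append(coloc_results_to_frame(results, config.condition, fov.field_id))
        try:
            area_results.append(classify_colors(
                fov, threshold_red=config.colorarea_t_red,
                threshold_green=config.colorarea_t_green))
        except Exception as exc:
            raise RuntimeError(f"colour-area stage failed on {fov.field_id}: {exc}") from exc

    per_cell = pd.concat(per_cell_frames, ignore_index=True)
    coloc_summary = summarize(per_cell, group_by="condition")
    area_per_field = pd.DataFrame([dataclasses.asdict(r) for r in area_results])
    area_per_field["flags"] = area_per_field["flags"].map(lambda f: ";".join(f))
    area_summary = aggregate_fields(area_results)

    paths = {
        "per_cell": out / "per_cell_coloc.csv",
        "coloc_summary": out / "coloc_summary.csv",
        "area_per_field": out / "colorarea_per_field.csv",
        "area_summary": out / "colorarea_summary.csv",
    }
    per_cell.to_csv(paths["per_cell"], index=False)
    coloc_summary.to_csv(paths["coloc_summary"], index=False)
    area_per_field.to_csv(paths["area_per_field"], index=False)
    area_summary.to_csv(paths["area_summary"], index=False)

    return {
        "per_cell": per_cell,
        "coloc_summary": coloc_summary,
        "area_per_field": area_per_field,
        "area_summary": area_summary,
        "paths": paths,
    }
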