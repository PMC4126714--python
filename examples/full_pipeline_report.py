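"""The whole pipeline: simulate two conditions, segment, measure, report.

Runs simulate -> segment -> per-cell colocalization + per-field colour
areas -> summary tables for a high-overlap and a tag-loss condition, and
prints the standard report layout (n cells, Pearson R, M1, M2 as
mean +/- SD; colour relative areas per field).
"""

import tempfile
from pathlib import Path

from coloctop import RunConfig, SimParams, run_pipeline

out_root = Path(tempfile.mkdtemp(prefix="coloctop_demo_"))

for condition, green_loss in (("intact_tag", 0.0), ("cleaved_tag", 0.5)):
    sim = SimParams(phenotype="dispersed_punctae", n_cells=2,
                    image_shape=(160, 160), cell_radius=30, n_structures=12,
                    true_overlap=0.8, green_loss=green_loss, psf_sigma=1.2,
                    background_level=0.0, photon_scale=4.0, read_noise_sd=2.0)
    cfg = RunConfig(sim=sim, n_fields=4, condition=condition,
                    segmentation="truth", threshold_mode="costes",
                    colorarea_t_red=300.0, colorarea_t_green=300.0,
                    out_dir=str(out_root / condition), seed=17)
    out = run_pipeline(cfg)
    print(f"\n=== {condition} (green_loss={green_loss}) ===")
    print(out["coloc_summary"].to_string(index=False))
    print(out["area_summary"].to_string(index=False))

print(f"\nPer-cell and per-field CSVs written under {out_root}")
print("Tag cleavage leaves Pearson/M2 high but drops M1 and shifts the "
      "colour balance from yellow toward red-only area.")
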