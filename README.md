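# coloctop

Per-cell colocalization analysis of two-channel fluorescence micrographs,
with a ground-truth simulator and absolute qPCR quantification.

## The problem

When one protein is labelled with two antibodies — say an N-terminal
antibody in the red channel and a C-terminal epitope tag in the green
channel — the degree to which the two signals co-occur is evidence about
where each terminus of the protein is accessible.  Microscopists quantify
this with ImageJ's JACoP plugin: per-cell Pearson correlation, Mander's
overlap coefficients under the Costes automatic threshold, and a
field-level "relative area" breakdown of overlapping versus single-channel
pixels.  `coloctop` reimplements that workflow as a tested, scriptable
Python library, and adds a synthetic-micrograph simulator with known
ground truth so every stage can be validated quantitatively — which the
point-and-click workflow never allows.

Intended users: cell biologists and image analysts quantifying two-channel
co-staining (membrane-trafficking proteins such as the IFITM family being
the motivating case), and method developers who need a colocalization
stack whose estimators are benchmarked against ground truth.

## The statistics

Over a pixel region (one segmented cell), with red intensities $R_i$ and
green intensities $G_i$:

* **Pearson's R** — $r = \sum_i (R_i-\bar R)(G_i-\bar G) \big/
  \sqrt{\sum_i (R_i-\bar R)^2 \sum_i (G_i-\bar G)^2}$, computed on raw
  pixels without thresholding.
* **Mander's coefficients** — $M_1 = \sum_{i: G_i > t_G} R_i \big/ \sum_i R_i$
  (the overlap of red in pixels that are green) and $M_2$ symmetrically
  (green in pixels that are red).
* **Costes automatic threshold** — fit $G = aR + b$ by least squares, then
  lower $t_R$ from the intensity maximum with $t_G = a t_R + b$ and stop at
  the highest $t_R$ for which the pixels *below* both thresholds satisfy
  $r \le 0$: the thresholds that separate correlated signal from background.
* **Relative colour areas** — a disjoint three-way pixel classification per
  field: "yellow" = above threshold in both channels (an AND image),
  "red" = above-threshold red with yellow removed, "green" =
  above-threshold green with yellow and red removed; areas reported as
  fractions of the classified union.  An excess of red over green area is
  the signature of lost green (C-terminal tag) signal.
* **qPCR copies per cell** — standard curve $C_t = a\,\log_{10}(\text{copies}) + b$
  from a dilution series; amplification efficiency $10^{-1/a} - 1$;
  copies per cell = copies in the 100 ng reaction ÷ (cells per 100 ng RNA),
  where cells per 100 ng = $n_\text{cells} / \text{RNA(ng)} \times 100$.

The simulator generates two-channel fields of three staining phenotypes
(plasma-membrane ring, dispersed cytoplasmic punctae, tight perinuclear
cluster) with a controllable true co-labelled fraction (`true_overlap`),
structure-level loss of the green channel (`green_loss`, modelling tag
cleavage), Gaussian PSF blur, Poisson shot noise, Gaussian read noise and
8/16-bit quantization — and records per-cell ground truth for parameter
recovery.

## Worked example

```python
from coloctop import SimParams, coloc_per_cell, simulate_field

params = SimParams(phenotype="dispersed_punctae", n_cells=2,
                   image_shape=(160, 160), cell_radius=30, n_structures=12,
                   true_overlap=0.6, psf_sigma=0.0, background_level=0.0,
                   photon_scale=0.0, read_noise_sd=0.0, seed=7)
field, mask, truth = simulate_field(params)
for res, cell in zip(coloc_per_cell(field, mask, threshold_mode="none"),
                     truth.cells):
    print(f"cell {res.cell_id}: M1 = {res.m1:.4f} "
          f"(ground truth {cell.realized_overlap:.4f})")
```

prints

```
cell 1: M1 = 0.6000  (ground truth 0.6000)
cell 2: M1 = 0.6000  (ground truth 0.6000)
```

— on a noise- and blur-free field, Mander's M1 returns the simulator's
true co-labelled intensity fraction exactly.  With PSF blur (σ = 1.2 px)
and high-SNR shot noise, the Costes-thresholded M1 recovers it to
`mean |M1 error| = 0.039` over 10 seeds (see
`examples/simulate_and_measure.py`).

The end-to-end report (`examples/full_pipeline_report.py`) compares an
intact-tag condition against one where half the structures have lost the
green channel:

```
=== intact_tag (green_loss=0.0) ===
 condition  n_cells  pearson_r_mean  ...  m1_mean    m1_sd  ...  m2_mean
intact_tag        8        0.882486  ... 0.825292 0.018385  ... 0.987543
colour  mean_frac  sd_frac  n_fields
yellow   0.718889 0.009686         4
   red   0.239974 0.006978         4
 green   0.041137 0.003851         4

=== cleaved_tag (green_loss=0.5) ===
  condition  n_cells  pearson_r_mean  ...  m1_mean    m1_sd  ...  m2_mean
cleaved_tag        8        0.594009  ... 0.453178 0.101167  ... 0.978701
colour  mean_frac  sd_frac  n_fields
yellow   0.370870 0.067041         4
   red   0.606384 0.074838         4
 green   0.022746 0.009253         4
```

Tag loss leaves M2 high (green still sits on red) while M1 and the yellow
area fall and the red-only area rises — the quantitative signature of a
cleaved C-terminal tag.

Each script in `examples/` demonstrates one capability: simulation +
recovery, the Costes threshold, colour areas under tag loss, qPCR copies
per cell, and the full pipeline.  A thin CLI mirrors the library:
`coloctop simulate|analyze|colorarea|qpcr|report --help`.

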