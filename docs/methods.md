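# Methods

## Colocalization estimators

All statistics operate on unsigned-integer 2D rasters over boolean pixel
regions derived from a label mask (0-based, row-major coordinates).

**Pearson's R** is the plain product-moment correlation of the two
channels over the region, computed on raw intensities with no threshold
and no background subtraction.  It is undefined (NaN, with a flag on the
per-cell result) when a channel is constant over the region; an empty
region is an error.

**Mander's coefficients** are intensity fractions at strict thresholds:
M1 = Σ red over pixels with green > t_green ÷ Σ red over the region, and
M2 with the channels swapped.  The orientation is fixed as *M1 = overlap
of red in pixels that are green*.  A zero channel sum makes the
corresponding coefficient NaN (flagged), never silently 0.  Because the
denominator is the raw regional sum, M1/M2 are only unbiased estimates of
a co-labelled signal fraction when the background is negligible; this is
a property of the coefficients themselves, not of this implementation,
and it is why the recovery experiments below use background-free images.

**Costes automatic threshold.**  Green is regressed on red by ordinary
least squares (the behaviour of the common ImageJ implementation;
orthogonal regression is deliberately not used).  The red threshold scans
downward from max(red) in steps of 1 intensity unit (configurable), with
t_green = a·t_red + b, and the procedure returns the highest t_red whose
*sub-threshold* pixels (red < t_red and green < t_green) have Pearson ≤ 0.
Ties resolve to the higher threshold by construction of the downward
scan.  Where the sub-threshold correlation is undefined (fewer than two
pixels, or a constant channel) the scan continues.  Two non-ideal cases
are surfaced honestly rather than hidden:

* slope ≤ 0 (anti-correlated channels): the procedure does not apply;
  per-channel Otsu thresholds are returned with a
  `costes_not_applicable` flag;
* no threshold achieves non-positive sub-threshold correlation (typical
  for strongly colocalized cells, where PSF tails keep even dim pixels
  positively correlated): the scan terminates at the bottom of the range
  with a `scan_exhausted` flag and the final sub-threshold correlation
  reported.

**Per-cell analysis** computes Pearson on raw pixels and M1/M2 under a
selectable threshold mode — `costes` (default, fitted per cell), `fixed`,
or `none` (zero thresholds) — one result per label, with per-cell
failures flagged on that cell only.

## Three-colour relative areas

Pixels of a field are partitioned sequentially into disjoint sets:
yellow (both channels above threshold), then red (above-threshold red
minus yellow), then green (above-threshold green minus yellow and red).
The AND step has two semantics: `intersection` (default — binarize each
channel at its threshold, intersect; on binarized images this equals the
bitwise AND of masks) and `minimum` (pixelwise minimum of the grayscale
channels, thresholded as an image).  Thresholds default to Otsu's method
per examined image, are overridable per step, and are echoed into the
result for audit.  Fractions are of the classified union, so they sum
to 1 whenever any pixel is classified; an all-empty classification is
flagged `no_signal` with NaN fractions.  Aggregation across fields is at
the field level (mean and sample SD of the per-field fractions), never
pixel-pooled.

When comparing conditions (e.g. a green-loss sweep), thresholds should be
held fixed across the series: a per-image Otsu threshold on a channel
that the condition has nearly emptied lands in the noise floor and
misclassifies background as signal.  The pipeline exposes fixed
thresholds for exactly this use.

## Segmentation

Default: Otsu threshold of the red+green sum image (after Gaussian
smoothing, σ = 2 px), morphological closing (radius 6 px) to bridge the
gaps of punctate stains into a cell footprint, hole filling, then
watershed — seeded from the Otsu-thresholded nuclei channel when present,
from distance-transform maxima otherwise — with watershed-line pixels
assigned to background so per-cell sums never double-count.  Regions
below `min_area` are dropped and labels renumbered; an empty result is an
explicit "no cells found" error that reports the applied threshold.  A
user-supplied label mask can be validated and passed through instead
(`method="provided_mask"`), preserving the manual-ROI workflow.

For ring-like (membrane) stains the segmented footprint matches the cell
and its centroid tracks the true center to ~1 px; for punctate stains the
footprint is the stained region, whose centroid can sit several pixels
from the geometric cell center — counts, not centroids, are the reliable
readout there.

## The simulator

Each field contains `n_cells` disk-shaped cells (radius `cell_radius`,
default 40 px in a 512×512 field — a scale at which punctae of radius
1–3 px span 3–7 blurred pixels, as in typical high-magnification confocal
data), placed by rejection sampling with centers ≥ 2·radius + 4 px apart;
an over-packed request is an explicit error, never a silent overlap.
Each cell gets an offset nucleus and a set of structures by phenotype:

* `membrane_ring` — a 3 px annulus at the cell edge, partitioned into
  `n_structures` angular arcs (the "structures" for green assignment);
* `dispersed_punctae` — disks of radius 1–3 px scattered in the
  cytoplasm with centers ≥ `structure_min_sep` (default 8 px) apart:
  dispersed vesicles are modelled as optically resolvable objects, which
  is also the regime in which structure-level colocalization is
  recoverable from blurred images at all;
* `perinuclear_cluster` — the same disks packed tightly against the
  nucleus (exponential radial offsets, no separation constraint): the
  deliberately hard, partially unresolvable case.

**Overlap bookkeeping.**  All structure pixels carry an integer red
amplitude (default 1200 ADU).  Green (the C-terminal tag channel) is
assigned at whole-structure granularity in a shuffled greedy order until
the red-intensity-weighted green fraction reaches `true_overlap`; the
residue is absorbed by partially greening the smallest remaining
structure, inside which one split pixel has its red amplitude adjusted so
the realized fraction lands on the target exactly.  Confining the partial
assignment to the smallest structure bounds the sub-structure mixing that
PSF blur later introduces to a few pixels per cell.  The adjusted
amplitude is rounded to keep the raster integer-valued; for overlap
fractions whose reduced denominator divides the amplitude (e.g. 0.6 with
amplitude 1200) the realized fraction is exact, otherwise it is within
~1/amplitude of the request — and the *realized* value, recomputed from
the noiseless rasters, is what the ground-truth record stores.
`green_loss` then zeroes the green channel of a round(green_loss ×
n_structures) subset of whole structures, after which the realized
overlap is recorded.

**Degradation model**, in fixed order: Gaussian PSF blur (σ =
`psf_sigma`, default 1.2 px) → constant background (`background_level`)
→ Poisson shot noise at gain `photon_scale` ADU/photon (expected counts =
intensity/gain; 0 disables) → Gaussian read noise (`read_noise_sd`) →
rounding, clipping and casting to 8- or 16-bit.  A single
`numpy.random.Generator` seeded from `SimParams.seed` drives everything,
so identical parameters give bit-identical fields.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: 3D structure and optical sectioning (one
2D plane stands in for confocal projections), spectral bleed-through,
uneven illumination and structured background, autofluorescence, cell
shape variability beyond disks, and chromatic misregistration.  Its role
is to give the estimators a known answer, not to be photorealistic.

## Recovery experiments and problem sizes

The validation suite runs at desk scale: 160×160 px fields, 2 cells of
radius 30 px, 12 punctae per cell, amplitude 1200, shot noise at gain 4
(≈300 photons per signal pixel, SNR ≈ 17) and read noise 2 — chosen so
the whole suite and the acceptance script complete in seconds while the
per-pixel statistics match the default 512×512 regime.  Recovery of
`true_overlap` by Costes-thresholded M1 is asserted as a mean absolute
error ≤ 0.05 over 20 seeds (measured ≈ 0.04); noise-free recovery is
exact.  Background is zero in these experiments because Mander's
coefficients use raw sums (above): with a constant background of b ADU
over a region of N pixels, M1's denominator inflates by b·N and the
coefficient no longer estimates the co-labelled fraction at any SNR.
Real-data practice is to background-subtract before computing Mander's
coefficients; the estimator itself is faithful to the raw-sum definition.

The qPCR slope-recovery check (Gaussian Ct noise, SD 0.1, five standards
over four decades) asserts the mean absolute slope error over 50
simulated series ≤ 0.05; the per-fit sampling SD is 0.1/√10 ≈ 0.032, so
individual fits legitimately stray beyond 0.05.

## qPCR module

The standard curve is an ordinary least-squares line of Ct on
log10(copies), requiring ≥ 3 standards spanning ≥ 2 decades with strictly
decreasing Ct (violations name the offending standard).  Efficiency =
10^(−1/slope) − 1.  Copies in a reaction = 10^((Ct − intercept)/slope);
copies per cell divides by the cell-equivalents of the 100 ng RNA input,
n_cells/total_RNA_ng × 100.  A Ct outside the standards' range is
extrapolated with a recorded warning.  Replicate Cts are averaged before
curve lookup; the implied copy-number SD uses the first-order delta
method, |copies·ln10/slope|·SD(Ct).

## Reporting conventions

Summary tables report mean ± sample SD (ddof = 1) per group, with
undefined (flagged) cells excluded metric-wise and the exclusion counts
shown; a single contributing field reports SD 0 with a flag.  Every
summary is recomputable from the per-cell / per-field CSVs written next
to it, and a pipeline run echoes its full configuration (including the
seed) as JSON, from which the run is exactly reproducible.

## Known limitations

* Pearson is computed on raw pixels only (no thresholded-Pearson variant).
* The Costes significance test by pixel scrambling, Li's ICQ and the Van
  Steensel cross-correlation are not implemented.
* Segmentation is intensity-based; heavily touching cells or empty
  channels defeat it (use a provided mask).
* The three-colour classification is threshold-sensitive by design; its
  cross-condition comparisons are only meaningful at fixed thresholds.
* 2D only, one field per file pair; no z-stacks or time series.
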