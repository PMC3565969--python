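# Methods

## Overview

`rbcqpi` reconstructs quantitative phase maps from off-axis interferograms,
segments individual red blood cells (RBCs), and reduces each cell to a
vector of morphological parameters and each sample to hematology indices
(MCV, RDW) plus parameter distributions. The output of a run is numbers —
a per-cell CSV and a kilobyte-scale text summary — not images. A phantom
generator produces ground-truthed synthetic scenes so the whole chain can
be validated without instrument data.

## Physical model

A transparent cell of thickness `h(x, y)` and refractive-index contrast
`Δn = n_cell − n_medium` delays the illumination by a phase

    φ(x, y) = (2π / λ) · Δn · h(x, y).

The cell index follows the linear hemoglobin law `n_cell = n_w + β·C`, with
`C` the mean cell hemoglobin concentration (MCHC, g/dL) measured
independently (e.g. by an impedance analyzer) and supplied as configuration.
Defaults: `n_w = 1.334`, `β = 0.00196 dL/g` (standard for hemoglobin at
visible wavelengths), `n_medium = 1.337` (PBS + 0.1 % albumin),
`λ = 550 nm` (effective center of a white-light source), pixel pitch
`0.125 µm` at the sample plane. All are overridable; the literature gives
the linear law but instrument-specific constants must come from the user.
`phase_to_height` / `height_to_phase` are pure linear maps; clamping of
negative reconstructed heights happens only in the morphology stage so the
physics operations stay side-effect-free.

## Interferogram model and phantom

The off-axis fringe pattern is

    I(x, y) = A · [1 + m · cos(2π u₀ x + φ(x, y))] + ε,

quantized to the camera bit depth (16-bit default). Defaults: carrier
`u₀ = 0.25` cycles/pixel (4 px per fringe; the sampling floor is 3 px per
fringe and the model refuses anything finer), contrast `m = 0.8`, mean
intensity 2000 counts, additive Gaussian noise with σ = 1 % of the mean
(an optional Poisson flag adds shot noise). These emulate a bright,
high-contrast common-path instrument; they are design values, since fringe
contrast and camera noise are instrument-specific.

Scenes add three nuisance fields shared by a sample frame and a cell-free
background frame: a smooth low-order aberration (random quadratic plus a
gentle sinusoid, 0.5 rad peak by default), static dirt (Gaussian phase
blobs, ≤ 1 rad), and the per-frame camera noise (independent between the
two frames, as in a real background acquisition).

Cell thickness profiles (all circularly symmetric, rescaled so the
*discrete* integral hits the requested volume exactly, which makes
per-cell volume ground truth exact by construction):

* **biconcave** — Evans–Fung parametric normal-RBC profile
  `h(r) = √(1−ρ²)(C₀ + C₂ρ² + C₄ρ⁴)`, ρ = r/R, with the classic
  coefficients (0.81, 7.83, −4.39 µm at R = 3.91 µm), height-rescaled to
  the target volume.
* **spherocyte** — a compact dome `h = H(1−ρ²)^{3/2}` with aspect
  `H = 1.4 R`. A literal sphere's projected chord profile has a
  vertical-slope rim whose spatial bandwidth is unbounded: it cannot be
  carried by a finite fringe carrier nor integrated accurately by Monge
  quadrature (the discretized surface area then falls below the sphere
  bound and sphericity exceeds 1). The bounded-slope dome represents the
  same "high-sphericity compact cell" phenotype while remaining resolvable.
* **flat_disc** — cylinder (test shape).
* **platelet** — low parabolic dome, volume strictly below 20 fL.

Surface-area ground truth is computed per cell by Monge quadrature of the
analytic profile on a 4× oversampled grid. Populations draw RBC volumes
from a normal law with `sd = RDW/100 × mean`, truncated above the 20 fL
platelet threshold (the draw is rejected as infeasible if less than 1 % of
the mass lies above the cut); platelet volumes are normal (9 ± 2 fL,
clipped below 20). Cells are placed by rejection sampling with ≥ 1 µm
edge-to-edge clearance and a 3 µm border margin; populations that do not
fit on one frame spill onto additional frames.

What the phantom does **not** emulate: partial-coherence (white-light)
speckle and halo, diffraction at cell edges (the forward model is a pure
phase delay), focus drift, touching or overlapping cells, and reticulocyte
substructure. Passing the recovery tests therefore demonstrates the
correctness of the processing chain on well-sampled, well-separated cells,
not robustness to every instrument artifact.

## Phase reconstruction

1. **Carrier estimation** — dominant non-DC peak of the power spectrum in
   the `u > 0` half-plane; a peak below 3× the spectral noise floor
   (median non-DC magnitude) raises a no-fringe error.
2. **Demodulation** — isolate the first-order lobe with a circular hard
   window centered at the carrier, roll it to baseband by the nearest
   integer bin, inverse transform, take the argument; output wrapped to
   [−π, π). The pipeline default window radius is 0.7·|carrier|. The lobe
   separation constraint only requires radius < |carrier|; a larger window
   passes more of the cell's edge spectrum, and with a constant-amplitude
   carrier the baseband lobe is a pure DC spike, so the wide window costs
   only a modest noise increase. At 0.5·|carrier| the truncation of the
   biconcave rim spectrum dominates the reconstruction error; at 0.7 the
   error over cell interiors drops roughly threefold. Any sub-bin carrier
   residual is a linear tilt shared by sample and background frames, which
   the background subtraction cancels.
3. **Unwrapping** — reliability-ordered (quality-guided) 2D unwrapping,
   with the result snapped onto the congruence contract
   `out = in + 2πk, k ∈ ℤ` exactly at every pixel. Residues are counted
   (curl of the wrapped gradient) and logged; residue-laden fields are
   unwrapped best-effort.
4. **Background subtraction** — pixel-wise difference of the unwrapped
   sample and background maps; the global offset is fixed by the mode of a
   coarse (128-bin) histogram, refined as the median within the modal bin
   ±1. In a dilute smear the cell-free area dominates, so the mode is the
   empty-field level; this is robust to cell content, unlike the mean.

Accuracy guarantees exclude a 16-pixel border margin and the outermost
~2 px of each cell footprint, where the analytic profiles' edge slope
diverges (infinite local bandwidth); "cell interior" in the tests means
the true footprint eroded by 2 px. On noiseless in-bandwidth phantoms the
reconstruction error over interiors is ≈ 0.012 rad RMS (the acceptance
bound is 0.02 rad).

## Segmentation

A single global threshold `τ = 0.3 rad` (configurable; the level is a
design value) separates cells from the background of the corrected phase
map. Connected components are labeled with the data-parallel
**label-equivalence** scheme: every foreground pixel starts with its own
linear index; a *scanning* pass assigns each pixel the minimum label in its
neighborhood (4- or 8-connectivity, default 8 since cells are blobs) and
records the discovered equivalences in a reference table; an *analysis*
pass resolves each label to the root of its equivalence chain; the passes
alternate until a fixpoint, then labels are compacted to 1..K. The
resulting partition is identical (up to relabeling) to flood fill, which
is asserted against `scipy.ndimage.label` as an independent oracle.
Termination is guaranteed: the label multiset strictly decreases each
scanning pass. An optional pre-filter removes specks under 10 px.

Objects touching the image border are discarded (their volume would be
truncated), and objects with integrated volume < 20 fL are excluded — the
platelet cut used for all RBC statistics.

## Per-cell morphology

* `PA` = pixel count × pitch²; equivalent diameter `2√(PA/π)`.
* `V` = Σ h · pitch² over the mask (negatives clamped, count recorded).
* `SA` = Monge top-surface quadrature `√(1 + h_x² + h_y²)` + PA for the
  flat bottom (cell rests on the coverslip). Gradients: central differences
  where both in-axis neighbors are inside the mask, one-sided at mask
  edges. Side walls of discontinuous profiles are deliberately not counted
  (a flat slab reports SA = 2·PA).
* Sphericity `Ψ = π^{1/3}(6V)^{2/3}/SA` (1 for a sphere).
* `MCD` — the cited sphero-cylinder model (a cylinder with hemispherical
  caps holding the cell's SA and V) gives `π D³ − 3·SA·D + 12·V = 0`; the
  smallest positive root is the physical diameter (the larger root violates
  the positive-cylinder-length constraint). A sphere gives exactly `D = 2r`
  (double root). Near-spherical discretized cells whose quadrature SA dips
  a hair under the sphere bound fall back to the equal-volume-sphere
  diameter (tolerance 10⁻³ on Ψ); wall-dominated shapes with Ψ further
  above 1 keep their record with MCD = NaN and a warning.
* Extended set: perimeter (4-direction Crofton estimator by default —
  unbiased on smooth convex shapes, so circularity `4π·PA/perimeter²` of a
  disc converges to 1; weighted-contour and crack-length variants behind a
  flag), eccentricity from second central moments (with the 1/12
  unit-pixel correction), thickness extrema and mean, integrated density
  (Σ phase over the mask, rad·px — phase, not height, is summed),
  and population-normalized variance/skewness/raw kurtosis of the height
  values (a constant field reports 0/0 with a degeneracy flag).

## Population statistics

MCV = arithmetic mean of volumes; RDW = 100 × sample (n−1) sd / mean.
Quartiles use linear interpolation; histograms use fixed bin widths
(1 fL for volume, 5 µm² for surface area by default). The summary is a
flat key-value + histogram-table text file, a few kB for thousands of
cells; per-cell CSV rows are ~200 bytes, so 10⁴ cells stay well under 5 MB.

## Problem sizes and determinism

Validation uses 512×512 frames at 0.125 µm pitch (a 64×64 µm field,
roughly 15–30 cells per frame), 200-cell populations for recovery and
120-cell populations per anemia regime — enough for the law-of-large-number
checks while keeping a full run in seconds on one core. All randomness
(population draws, placement, aberration, dirt, noise) flows from explicit
seeds through `numpy.random.default_rng`; identical seeds reproduce
bit-identical TIFFs and CSVs.

## Known limitations

* The Fourier demodulator assumes a single dominant carrier; crossed or
  curved fringes are out of scope.
* Touching cells are not split (no watershed); the dilute-smear assumption
  is load-bearing.
* Frames are analyzed independently and records concatenated; cells seen
  in overlapping fields of a translated smear would be double-counted.
* Sphericity and MCD inherit the Monge convention of ignoring vertical
  walls; they are meaningful for smooth cell-like profiles, not for
  thick cylinders.
* MCHC is a per-sample scalar; per-cell hemoglobin variation maps into
  apparent volume variation.
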