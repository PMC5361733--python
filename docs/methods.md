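# Methods

## Overview

`fociscope` quantifies DNA double-strand-break (DSB) repair foci — γH2AX or
53BP1 immunostains — in 3D wide-field fluorescence stacks, and reproduces the
statistical reporting layer of a repair-kinetics study: per-condition ×
cell-cycle-phase summaries of foci per cell, fold-changes between conditions,
two- and multi-group hypothesis tests, and post-irradiation time courses.
Because no raw microscopy data are distributed with the package, a synthetic
image generator with exact ground truth is a first-class component: every
analysis stage is validated by parameter recovery against that truth.

The analysis chain is:

1. **Nucleus segmentation** of the nuclear-stain channel: Gaussian
   preprocessing → two-level (three-class) Otsu thresholding → hysteresis
   thresholding → 26-connected instance labeling with minimum-size and
   border filters.
2. **Focus counting** in the marker channel: lateral Gaussian smoothing →
   extended-maxima (h-maxima) transform → maximum-spot-size filter →
   centroid-based assignment of each maxima component to a nucleus.
3. **Cell-cycle gating**: per-nucleus total EdU intensity, then a per-slide
   Otsu threshold on the linear-scale totals splits EdU-negative (G1) from
   EdU-positive (S/G2) cells.
4. **Statistics**: group means with SEM = SD/√n, fold-changes and percent
   increases, Student's t (two groups), one-way ANOVA with Tukey HSD
   (three or more), and percent-of-peak repair time courses.

## The synthetic-data generator

The generator emulates the acquisition geometry of the emulated study:
fields of 30 slices at 3 µm z-spacing, 1392 × 1040 px, 124 × 124 nm pixels,
with three co-registered channels (nuclear stain, focus marker, EdU).
Its generative model is the simplest structure consistent with the summary
statistics it must reproduce:

- **Cell-cycle phase** is Bernoulli with EdU-negative probability
  `frac_g1` (0.872 for the fibroblast-like default).
- **Foci per cell** are Poisson with a phase-specific rate
  (`lambda_g1`, `lambda_sg2`); the default rates are the published
  condition means carried in the packaged reference table.
- **Nuclei** are non-overlapping axis-aligned ellipsoids that do not touch
  the field border. A per-nucleus scale is drawn uniformly from
  4.5–6.3 µm (lateral semi-axis) with ±5 % per-axis jitter and an axial
  semi-axis of 1.5–2.5 slices tied to the same scale. The jittered scale
  gives a nuclear-volume CV of ≈ 20 %, matching cultured fibroblast nuclei;
  a fully independent per-axis draw would produce 4-fold volume ratios,
  which both looks wrong and (more importantly) broadens the EdU-total
  distributions enough to degrade any linear-scale threshold on them.
- **Nuclear channel**: base intensity 100 counts with a radial chromatin
  gradient (1.3× at the centre falling to 0.7× at the rim). The gradient
  matters: a perfectly flat nucleus on a flat background has only two
  intensity classes, and a three-class Otsu would then split the background
  noise instead of the foreground — an artefact of flat phantoms, not of
  real stained nuclei.
- **Foci**: in-plane Gaussian spots (σ = 1 px by default, diffraction-class
  at 124 nm pixels) of peak amplitude 200 counts, rendered in the focus's
  z-slice only (spot extent ≪ 3 µm slice spacing). Positions are drawn
  uniformly in the 0.9-scaled nucleus ellipsoid as a **hard-core point
  process**: two foci in the same or adjacent slices keep ≥ 8 px (≈ 1 µm)
  lateral separation. Real repair foci are ~0.5–1 µm chromatin domains; a
  sub-resolution pair is one spot to any counting method, so ground-truth
  counts are counts of *resolvable* foci.
- **EdU channel**: a per-cell level filling the nucleus — 20 counts
  (negative) or 400 counts (positive) with 10 % per-cell CV. The resulting
  per-cell totals are bimodal with ≥ 6 SD separation at the level scale.
- **Noise**: additive Gaussian read noise (default SD 5 counts, 16-bit-class
  camera scale), clipped at zero. Bit depth and background level are not
  derivable from the emulated study and are declared defaults.

What the generator does **not** emulate: a full 3D PSF (no axial blur or
out-of-focus haze), photobleaching, uneven illumination, touching or mitotic
nuclei, apoptotic morphology, and intra-nuclear marker background. Passing
recovery tests therefore demonstrate correctness of the algorithmic chain
under clean imaging conditions, not robustness to every real-world artefact.
The thresholds of the detector (height 80, maximum size 800) were set
empirically in the original analysis for real image statistics; on the
synthetic data they sit comfortably inside wide margins (smoothed spot
peak ≈ 100 over background ≪ 10).

## Numerical and algorithmic choices

- **Connectivity** is 26-connected everywhere in 3D.
- **Two-level Otsu** is an exact exhaustive search over all threshold pairs
  (vectorised with prefix sums), maximising between-class variance of the
  three-class partition of a 256-bin histogram; ties are broken toward the
  lexicographically smallest pair, with a 1e-9 relative tolerance so exact
  rational ties are not decided by floating-point noise. Thresholds are
  reported as bin edges; a voxel is in the upper class iff value ≥ threshold.
- **Hysteresis** keeps all voxels ≥ t_low 26-connected to a seed ≥ t_high,
  with the lower Otsu level as t_low and the upper as the seed threshold —
  the only reading under which a two-level Otsu parameterises a hysteresis
  segmenter. It is implemented directly (connected-component labeling plus
  seed intersection) because the library routine uses strict inequalities
  and 6-connectivity.
- **Otsu is computed per field** for segmentation and **per slide** (pooled
  fields) for EdU gating; cells exactly at the gate threshold are
  EdU-positive (documented tie rule).
- **Extended maxima** follow the classical definition: regional maxima of
  the morphological reconstruction (by dilation) of `volume − h` under
  `volume`. This is additive-offset invariant by construction. A volume
  whose total dynamic range is below `h` has no maxima of sufficient height
  and yields zero components (this also covers constant volumes, where the
  sole regional maximum spans the field). A merged multi-peak component
  counts as one focus — no declumping. The height criterion is applied
  before the size filter, and components are assigned to the nucleus label
  under their rounded centroid; components centred on background are
  discarded.
- **Smoothing for spot detection** is lateral-only: at 3 µm slices the
  axial σ implied by scaling a 1 px lateral σ is ≈ 0.04 px, i.e. nothing.
- **Maximum spot size** is interpreted in voxels of the maxima component,
  matching the pixel-based parameter conventions of the original software.
- **Segmentation size filter** defaults to 2000 voxels (≈ 0.09 pL at the
  default spacing) — well below the smallest simulated nucleus (~8000
  voxels), above debris scale. Components touching any volume face are
  dropped: the original workflow cropped whole cells by hand, which
  implicitly excluded cut-off nuclei. Watershed splitting of touching
  nuclei is deliberately absent; the generator guarantees separation and
  real clumps fall to the size filter.
- **Student's t** is the equal-variance form by default (Welch behind a
  flag); **Tukey HSD** uses the studentized-range distribution with
  Tukey–Kramer handling of unequal group sizes. SEM of a single-cell group
  is defined as 0 with a warning.
- **Fold reporting**: raw ratios are always retained; the formatted value
  is the nearest integer for ratios ≥ 10 ("18-fold") and one decimal below
  ("2.1-times", "4.6-times").
- **Repair time courses** express residual damage as
  100 · mean(t) / mean(0.5 h) for t ∈ {2 h, 6 h}, the 0.5 h point being the
  post-irradiation peak. Cell-level SEM is primary; region-level summaries
  can be had by grouping on `field_id`.
- **Determinism**: every stochastic step takes an explicit seed;
  field-level seeds are derived from the run seed with `SeedSequence`.
  Re-running a pipeline config with the same seed is byte-identical.

## Problem sizes in the validation suite

Recovery tests tile virtual slides from desk-scale fields
(14 × 360 × 360 voxels, 8 nuclei per field) at the standard voxel spacing:
per-cell statistics are unaffected by the tiling, and a ~500-cell slide
stays within desktop memory and a few minutes of CPU. Rate-recovery
scenarios run noise-free (the published acceptance conditions); gating
recovery runs at the default noise level. Population-level distribution
checks (law of large numbers, phase fractions) sample geometry on large
virtual volumes without rendering.

## Known limitations

- The EdU gate is a global two-class threshold; a three-state G1/S/G2
  separation (or DNA-content gating from the nuclear stain integral) is out
  of scope.
- Linear-scale Otsu on totals degrades when the EdU-positive class is both
  broad and heavily weighted (≈ 40 %+ of cells with a > 3× spread of
  totals); at the fibroblast-like balance it is accurate to < 1 %
  misclassification at slide scale (n ≥ 500).
- Counts are of resolvable maxima components; genuinely overlapping foci
  are undercounted by design.
- No sub-voxel localisation, no colocalisation between the two markers
  (they are stained on separate slides), no apoptosis/viability statistics.
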