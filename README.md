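# fociscope

Automated quantification of DNA double-strand-break (DSB) repair foci in 3D
fluorescence microscopy stacks, with cell-cycle-aware statistics.

## The problem

γH2AX and 53BP1 accumulate at DSB sites and form microscopically countable
nuclear foci, making foci-per-cell the standard single-cell readout of DNA
damage and repair. The count is strongly confounded by cell-cycle phase:
S/G2 cells carry replication-stress foci that can dwarf the damage signal.
A credible pipeline therefore has to (a) segment nucleus instances in 3D,
(b) count diffraction-scale bright spots inside each nucleus, (c) classify
each cell as EdU-negative (G1) or EdU-positive (S/G2) from a replication
label, and (d) report statistics stratified by phase. `fociscope` implements
that chain for wide-field stacks (e.g. 30 slices × 3 µm at 124 nm pixels),
plus a synthetic image generator with exact ground truth so the whole
pipeline is testable without any microscopy data. It is aimed at people
analysing irradiation/repair experiments (fibroblasts, iPSC/ESC lines) and
at anyone who needs a tested reference implementation of the classical
segmentation/spot-counting recipe below.

## Methods at the core

- **Nucleus segmentation**: Gaussian preprocessing (σ = 1 px), two-level
  Otsu thresholds (t₁ < t₂ maximising the three-class between-class
  variance σ²_B = Σ_k ω_k(μ_k − μ)²), hysteresis thresholding (keep voxels
  ≥ t₁ 26-connected to seeds ≥ t₂), then minimum-size and border filters →
  instance labels.
- **Focus counting**: the extended-maxima (h-maxima) transform,
  EMAX_h(f) = RMAX(R^δ_f(f − h)) — regional maxima of the morphological
  reconstruction of f − h under f — with spot height h = 80 counts and a
  maximum component size of 800 voxels; each surviving component is
  assigned to the nucleus under its centroid.
- **EdU gating**: per-cell total EdU intensity over the nucleus mask; a
  per-slide Otsu threshold on the linear-scale totals separates G1 from
  S/G2.
- **Statistics**: mean ± SEM (SD/√n) per condition × phase, fold-changes
  and percent increases, Student's t, one-way ANOVA + Tukey HSD, and
  percent-of-peak repair time courses 100·mean(t)/mean(0.5 h).

The synthetic generator draws Poisson foci counts with phase-specific rates
inside non-overlapping ellipsoidal nuclei and renders the three channels at
the acquisition geometry above; see `docs/methods.md` for the model, its
defaults and its limits.

## Worked example

Simulate and analyse an irradiated fibroblast-like slide (1 Gy, 0.5 h;
generative rates 19.89 foci/cell in G1, 45.49 in S/G2, 87.2 % EdU-negative):

```python
import fociscope as fs
from fociscope.pipeline import simulate_and_analyze_slide
from fociscope.stats import summaries_to_frame

cond = fs.ConditionParams(line_id="hDF", marker="gH2AX", dose_gy=1.0,
                          time_h=0.5, lambda_g1=19.89, lambda_sg2=45.49,
                          frac_g1=0.872, n_cells=8)
render = fs.RenderParams(shape_zyx=(14, 360, 360), noise_sd=5.0)
records, truths, gate = simulate_and_analyze_slide(cond, render, seed=0,
                                                   n_fields=8)
print(f"EdU gate threshold: {gate.threshold:.3g} summed counts -> "
      f"{gate.frac_neg_percent:.1f}% EdU-negative (true fraction 87.2%)")
print(summaries_to_frame(fs.summarize_foci(records)).to_string(index=False))
```

prints

```
EdU gate threshold: 6.02e+05 summed counts -> 84.4% EdU-negative (true fraction 87.2%)
line_id marker  dose_gy  time_h phase  mean_foci      sem  n_cells
    hDF  gH2AX      1.0     0.5    G1  20.166667 0.627659       54
    hDF  gH2AX      1.0     0.5   SG2  43.000000 2.290075       10
```

All 64 simulated nuclei were recovered; the G1 mean (20.2 ± 0.6 over 54
cells) sits within sampling error of the generative rate 19.89, and the
gate's EdU-negative percentage (84.4 % of 64 cells) brackets the true 87.2 %
at this small n. At slide scale (≥ 500 cells, tiled over many fields) the
recovered means land within 3 SEM and the gated fraction within a couple of
percentage points — that is exactly what the acceptance script measures.

A packaged reference table of published condition summaries is available for
worked examples:

```python
table = fs.load_reference_summary()
irr = fs.reference_mean(table, "hDF", "na", "gH2AX", "1Gy", "G1")      # 19.89
ctrl = fs.reference_mean(table, "hDF", "na", "gH2AX", "control", "G1") # 1.13
fs.format_fold(fs.fold_change(irr, ctrl))                              # 18.0
```

## Command line

Every stage is also a subcommand over plain TIFF/CSV intermediates:

```sh
fociscope simulate --config run.yaml --seed 0 --out fields/
fociscope segment  --stack fields/hDF_f000.tiff --out labels.tiff --table nuclei.csv
fociscope count    --stack fields/hDF_f000.tiff --labels labels.tiff \
                   --out cells.csv --spots spots.csv
fociscope gate     --cells cells.csv --out gated.csv --report gate.json
fociscope stats    --cells gated.csv --out summary.csv --tests tests.csv \
                   --timecourse tc.csv
fociscope run      --config run.yaml    # the whole chain, reproducibly
```

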