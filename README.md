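# marrowmap

Spatial niche statistics for longitudinal bone-marrow sections.

In acute myeloid leukaemia, where leukaemic stem cells (LSCs) sit along
the femur's long axis — proximal metaphysis (PM), central marrow (CM),
distal metaphysis (DM) — governs their quiescence, stemness and drug
resistance. Their position is set by CXCL12 gradients that the protease
DPP4 (on leukaemic cells) erodes and the stromal DPP4-inhibitor GPC3
(on N-cadherin⁺ mesenchymal stromal cells) locally protects. `marrowmap`
packages the quantitative toolkit for this kind of imaging study:

- **Regional quantification** — assign cells to PM/CM/DM by position and
  compute (optionally weighted) region fractions.
- **Distance-to-structure analysis** — exact Euclidean distances from
  cells to vessel/stromal primitives (segments, disks, points; surface,
  not centreline), 5-µm binned distance histograms, and the fraction of
  cells within a radius of the nearest structure.
- **Random-placement Monte-Carlo null** — repositions the observed number
  of cells uniformly over the real marrow mask, recomputes the mean
  nearest distance `n_sim` times, and flags an observed mean outside the
  grand mean (mean of simulated means) ± 3σ; z-score and one-sided
  empirical p included.
- **Two-sample Kolmogorov–Smirnov** comparison of distance distributions
  (exact ECDF-scan `D`, asymptotic Kolmogorov-series p).
- **Chemokine gradient indices** — per-region field means, PM/CM and
  DM/CM ratios, and the marrow-vs-plasma (BM/PB) orientation index.
- **Limiting-dilution analysis** — single-hit Poisson model
  `P(response | dose d) = 1 − (1 − θ)^d`, maximum likelihood frequency
  ("1 in N" = 1/θ), 95% CI on the complementary log-log scale (Wald, with
  a profile-likelihood option), fitted non-response curves, and
  likelihood-ratio comparison between groups.
- **Gated two-group testing** — Shapiro–Wilk + Brown–Forsythe gates
  selecting Student's t (pooled) or Mann–Whitney, as imaging studies
  conventionally report.
- **A seeded synthetic-section generator** — rectangular longitudinal
  sections with a PM/CM/DM partition, uniform vessel segments,
  metaphysis-enriched GPC3⁺ stromal hotspots, a CXCL12 field shaped by
  exponential source kernels with DPP4 degradation and bounded GPC3
  protection, chemotaxis-weighted cell placement, and single-hit
  limiting-dilution experiments — so every analysis runs end to end with
  no external data.

## Worked example

```python
import marrowmap as mm

cfg = mm.SimulationConfig(seed=7)                 # defaults: 1600x400 um section
geometry, vessels, stromal = mm.generate_section(cfg)
field = mm.compute_cxcl12_field(geometry, stromal, cfg)
cells = mm.place_cells(geometry, field, cfg.n_cells, cfg.attraction_beta, cfg.seed)

print(mm.region_proportions(mm.assign_region(cells, geometry)))
# {'PM': 0.474, 'CM': 0.106, 'DM': 0.42}

gi = mm.regional_field_summary(field, geometry)
print(gi.ratios)                                  # {'PM/CM': 3.05, 'DM/CM': 2.48}

null = mm.random_placement_null(cells, geometry, vessels, n_sim=1000, seed=7)
print(null.summary())
```

The region fractions show the chemotaxis-placed cells concentrating in
the metaphyses (47% PM vs 11% CM against area fractions of 30%/40%/30%),
and the field ratio PM/CM ≈ 3.1 is the protease-shaped gradient that
drives them there. The null-model summary prints

```
Random-placement null model
  simulations        : 1000
  cells per sim      : 500
  grand mean (um)    : 66.12
  sigma (um)         : 2.39
  observed mean (um) : 61.50
  z score            : -1.94
  outside 3 sigma    : False
  empirical p        : 0.02597
  status             : ok
```

i.e. these cells sit 61.5 µm from the nearest vessel on average, versus
66.1 ± 2.4 µm for randomly repositioned cells on the same map — closer
than chance but not beyond the 3σ verdict line (the cells here were
attracted to stromal hotspots, not to the vessels themselves).

Limiting dilution, from a simulated three-region transplantation assay:

```python
fit = mm.fit_single_hit(data, "PM")
print(fit.summary())
# Single-hit limiting dilution fit: group PM
#   frequency          : 1 in 116.4
#   95% CI             : 1 in 67.1 to 1 in 202.0
#   theta_hat          : 0.00859444
#   log-likelihood     : -17.6160
#   converged          : True
print(mm.compare_groups(data, "PM", "CM").summary())
# LDA comparison PM vs CM: LR = 14.2519 (df=1), p = 0.0001599
```

The "1 in 116" readout is the estimated tumour-initiating-cell
frequency: one PM cell in ~116 can re-initiate leukaemia, versus a much
rarer frequency in CM — the likelihood-ratio test puts the difference at
p ≈ 1.6 × 10⁻⁴.

## Command line

```bash
marrowmap simulate --config section.yaml --out sim/
marrowmap analyze --cells sim/cells.csv --structures sim/vessels.json \
                  --geometry sim/geometry.json --nsim 1000 --seed 7 --out report.json
marrowmap lda --data lda.csv --compare PM:CM --compare CM:DM --out lda_report.json
marrowmap run control --seed 7 --out runs/control
marrowmap compare runs/control/report.json runs/knockout/report.json
```

`run control` / `run knockout` execute the packaged scenario pair
(protease on + strong chemotaxis vs protease off + flattened
chemotaxis); every run writes cells CSV, structure JSON, the CXCL12
field as 32-bit TIFF, histogram/region CSVs and a deterministic
`report.json`. Validation errors exit with code 2.

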