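# Methods

## The analysis model

`marrowmap` treats a stained longitudinal femur section as a 2D point
pattern problem. The section is a rectangle with (0, 0) at the
proximal-top corner and x increasing distally; two boundaries b₁ < b₂
split the long axis into proximal metaphysis PM = [0, b₁), central
marrow CM = [b₁, b₂) and distal metaphysis DM = [b₂, L]. Intervals are
half-open on the left so every x maps to exactly one region. Cells are
labelled coordinates (µm) with categorical marks (gfp, kit, genotype);
vessels and stromal cells are geometric primitives (segments, disks,
points) with a radius.

### Distances

Cell-to-structure distances are exact Euclidean distances to the
primitive *surface*: centreline/centre distance minus radius, floored at
0, so a cell inside a vessel lumen reports 0. Surface rather than
centreline is used because an extravascular cell's biologically relevant
distance is to the vessel wall. Ties between equidistant primitives
resolve to the lowest index. A raster fallback (`mask_distances`, a
Euclidean distance transform on a structure mask) covers mask-only
inputs with ≤ ~1 pixel error; the exact path is preferred whenever
primitives exist.

### Distance histograms and proximity fractions

Histograms use left-closed bins [0, w), [w, 2w), … labelled by their
upper edge (bin width default 5 µm, the convention of intravital niche
studies: "5" means the 0–5 µm interval). A distance exactly on a bin
boundary goes to the right bin, making the labelling unambiguous.
`fraction_within(r)` counts distances strictly below r, which keeps it
identical to the first histogram bin fraction at r = w.

### Two-sample Kolmogorov–Smirnov

D is the supremum of |F₁ − F₂| scanned over the pooled sample points
(an exact ECDF computation, not an approximation). The p-value uses the
asymptotic Kolmogorov series at √(n₁n₂/(n₁+n₂))·D, the same limit
standard software applies at these sample sizes; below a combined n of
25 the exact permutation distribution is used instead.

### Random-placement null model

The question "are these cells closer to vessels than chance?" is
answered against a Monte-Carlo null that keeps the *real* structure map
and marrow mask and only randomizes the cells: each of n_sim simulations
redraws the observed number of cells uniformly over marrow pixels
(uniform pixel choice plus uniform in-pixel jitter) and records the mean
nearest-structure distance. The verdict compares the observed mean with
the grand mean (mean of simulated means) ± 3σ, where σ is the standard
deviation of the simulated means — the conventional printed rule. A
z-score and a one-sided empirical p (toward attraction, i.e. simulated
means ≤ observed, with the +1 correction) accompany it; the 3σ verdict
itself remains two-sided. If σ = 0 (structures cover the whole map) the
result carries an explicit `degenerate` status instead of a silent
verdict. n_sim defaults to 1,000: the Monte-Carlo error of the grand
mean (σ/√n_sim) is then ~30× smaller than the 3σ decision margin.

### Gradient indices

Regional field summaries average the chemokine field over marrow pixels
per region and report PM/CM and DM/CM ratios; the gradient counts as
"reversed" when CM exceeds both metaphyses (the niche-flattened
signature). The systemic index is the BM/PB ratio with reference
orientation plasma → marrow; BM/PB > 1 is the reversed state that
confines leukaemic cells inside the marrow.

### Gated two-group testing

Following common practice in this literature, group comparisons are
gated: Shapiro–Wilk normality per group and Brown–Forsythe variance
homogeneity (Levene's test on deviations from group medians — its
standard definition). If all three gate p-values exceed α (default
0.05, the conventional choice) a two-sided pooled-variance Student
t-test is run, otherwise the two-sided Mann–Whitney rank-sum test. Two
identical constant samples return a degenerate flag rather than a test.

### Limiting-dilution analysis

The single-hit Poisson model: an animal transplanted with d cells
responds unless none of the d cells is tumour-initiating, so
P(response) = 1 − (1 − θ)^d with θ the per-cell frequency. The exact
(1 − θ)^d form is kept rather than exp(−θd); they agree to < 0.5% at
typical doses but the exact form stays valid at small doses. The
binomial log-likelihood is maximized by bounded scalar search on the
log-odds of θ (deterministic bracket [−30, 30], tolerance 1e−12 — no
randomness in fitting). Frequencies are reported as "1 in N" with
N = 1/θ̂. The default 95% CI is a Wald interval on the complementary
log-log scale φ = log(−log(1−θ)) — the scale on which the likelihood is
closest to quadratic for this model — with the observed information
obtained by central second differences (h = 1e−5); a profile-likelihood
CI is available as an option. All-responding or none-responding data
make the likelihood monotone; these raise a boundary error naming the
unbounded direction instead of returning a sham estimate. Group
comparison is the likelihood-ratio test of one common θ versus separate
θs, referred to χ²(1); the statistic is clamped at 0 against ~1e−8
numerical slack. Mice are assumed exchangeable within a dose (no
mouse-level frailty).

## The synthetic-section generator

The generator emulates the *statistical structure* the analyses assume,
not the images themselves:

- **Geometry** — a 2D rectangle (one longitudinal plane), default
  1600 × 400 µm with region bounds at 30%/70% of the length, rasterized
  at `grid_resolution_um` (default 2 µm for the packaged scenarios; the
  mask machinery accepts any resolution). The marrow mask is the full
  rectangle; vessel lumina can optionally be excluded
  (`exclude_vessel_lumen`, default off — cell centroids may overlap
  vessel signal in real sections, and the convention is left explicit).
- **Vessels** — `n_vessels` (default 25) segments of length 80 µm and
  lumen radius 5 µm, centres uniform over marrow, isotropic
  orientation, endpoints clipped to the section.
- **Stromal hotspots** — `n_stromal` (default 40) N-cad⁺ points placed
  with PM/DM odds multiplied by `stromal_pm_dm_enrichment` (default 5)
  relative to CM, carrying a `gpc3_level` mark (default 1).
- **CXCL12 field** — the simplest form reproducing the qualitative
  biology:

      field(x) = [c₀ + Σᵢ A·exp(−d(x, sᵢ)/λ)] · [1 − k·(1 − prot(x))]
      prot(x)  = min(1, Σⱼ gpc3ⱼ·max(0, 1 − d(x, gⱼ)/R))

  with amplitude A = 1 (a.u.), decay length λ = 60 µm, baseline
  c₀ = 0.05, protease activity k = 0.7 and protection radius
  R = 40 µm. Absolute CXCL12 concentrations per region are not
  published, so amplitudes are unitless; the decay and protection
  lengths are of the order of the chemokine microdomains (tens of µm)
  reported for marrow niches. Degradation multiplies the *summed* field,
  protection is bounded at 1, and with metaphysis-enriched hotspots the
  construction yields mean(PM) > mean(CM) while k = 0 strictly raises
  CM — the control/knockout contrast. This is a generative stand-in; no
  reaction–diffusion PDE is solved.
- **Cell placement** — cells sample marrow pixels with probability
  ∝ field^β and jitter uniformly within the pixel; β = 0 is uniform.
  The default β = 2 reproduces metaphysis-dominant control patterns
  (PM fraction ≈ 0.35–0.65 against an area fraction of 0.3) without the
  winner-take-all collapse that larger exponents produce. The packaged
  pipeline splits cells into a stem-enriched kit⁺ half at β and a
  differentiated kit⁻ half at β/4, mirroring the observation that the
  stem fraction hugs the stromal hotspots hardest.
- **LDA simulation** — animals respond independently with probability
  1 − (1 − f)^dose; counts are binomial per dose.

Randomness contract: one integer seed; each generator stage (vessels,
stroma, cells, LDA, null model) draws from its own substream spawned
deterministically from it (`SeedSequence(seed, spawn_key)`), so adding a
stage never perturbs the others and every output is a pure function of
(config, seed).

### What the generator does *not* emulate

Real sections have irregular marrow boundaries, trabecular bone,
section-to-section thickness variation, segmentation noise, optical
blur and cell-size exclusion effects; vessels are curved and branching,
not straight segments; chemokine fields are dynamic. Tests passing on
synthetic sections therefore validate the *statistical machinery* —
calibration of the null, exactness of distances, recovery of known
frequencies — not the biology of any particular dataset.

## Scenario pipeline

The packaged `control` scenario uses the generator defaults; `knockout`
sets k = 0 (no degradation) and β = 0.8 (flattened chemotaxis),
mirroring the knockout phenotype of an evened-out distribution. A
scenario run writes every artefact (cells CSV, structures and geometry
JSON, field TIFF with JSON sidecar, histogram and region-fraction CSVs,
report JSON) and is byte-deterministic given the spec: two runs differ
only in the report timestamp. File formats round-trip to 1e−9 (the
field TIFF to float32 precision).

## Problem sizes

The test and acceptance runs use a 800 × 300 µm section at 2 µm
resolution with 15 vessels for the null-model experiments (200
calibration replicates and 100 power replicates at n_sim = 1,000 and
500 cells per pattern), the full 1600 × 400 µm default for the scenario
contrast (500 cells), and 500/200 simulations for limiting-dilution
recovery/power at doses {10, 100, 1000} with 20 animals per dose —
sizes at which the Monte-Carlo error of each reported quantity is small
against the effect being checked.

## Known limitations

- The calibration band on the null model's z-mean is checked with 200
  replicate experiments; the sampling error of that estimate
  (SE ≈ 0.07) is of the same order as the ±0.1 band, so individual
  batches can fall marginally outside it even though larger runs show
  the method unbiased.
- The Wald cloglog CI undercovers slightly for nearly-degenerate dose
  designs (single dose, few animals); the profile option is preferable
  there.
- The mask-based distance path inherits rasterization error (≤ ~1
  pixel plus the half-pixel padding of mask rasterization).
- 2D only: no attempt to model out-of-plane structures intersecting the
  section.
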