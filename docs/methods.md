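# Methods

## Problem and model

Estrogen receptor α (ERα) is scored clinically as a nuclear marker, but a
fraction of the receptor resides outside the nucleus (cytoplasm and plasma
membrane), where it drives non-genomic signaling implicated in endocrine
therapy resistance. Phosphor-integrated dots (PIDs) are ~150 nm fluorescent
nanoparticles bright enough to be counted as individual immunolabels, which
turns receptor quantification into a particle-counting problem with
preserved morphology.

`pidquant` implements the image-analysis side of that measurement:

1. **Spot detection.** PID puncta are diffraction-limited, so detection is
   a single-scale matched filter: the scale-normalized negative Laplacian
   of Gaussian `−σ²·∇²G_σ * I` at σ matched to the point-spread function
   (default 0.3 μm). Local maxima above `median + k·MAD` of the filtered
   response (default k = 8) are kept, deduplicated by greedy non-maximum
   suppression at a minimum separation (default max(2 px, 2σ)), and
   refined to subpixel centroids by an intensity-weighted mean over a
   `(2⌈2σ⌉+1)²` window of the background-subtracted image.
2. **Nearest-neighbor compartment assignment.** Nuclei are pathologist-
   delineated label masks. The Euclidean distance transform of the
   background gives each pixel its distance to the nearest nucleus
   *boundary/area pixel* (not the centroid) in μm, plus the arg-min
   nucleus label (equidistant ties go to the smaller label). A spot whose
   centroid pixel lies inside a nucleus is **nuclear** for that nucleus; a
   spot within `d_max` (default 4 μm, the calibrated value) of a nucleus is
   **extranuclear** for the nearest nucleus; anything farther is
   **unassigned** and excluded from all scores.
3. **Scores.** With per-cell counts `n_nuc` and `n_ext` over the cells of a
   sample: total score = mean(n_nuc + n_ext), nuclear score = mean(n_nuc),
   extranuclear score = total − nuclear (exact identity), and
   ENR = extranuclear / nuclear. ENR is a ratio of sample-level means —
   not a mean of per-cell ratios, which are undefined for cells with empty
   nuclei — and is itself undefined (`None`, with a warning) exactly when
   the nuclear score is zero. Fields are pooled cell-wise before averaging
   (a field with more cells weighs more); cells whose nucleus touches the
   field border have truncated extranuclear territory and are excluded by
   default.
4. **Distance calibration.** Where a membrane marker provides whole-cell
   masks, the per-cell truth is (spots in the whole-cell label) − (spots in
   the nucleus label). Sweeping candidate distances {2, 4, 6, 8} μm through
   the pipeline and correlating the estimated extranuclear score with this
   truth across samples (squared Pearson r²) selects the optimal distance;
   ties go to the smaller, more conservative distance. The correlation unit
   defaults to the sample (panels of samples spanning a range of expression
   levels); per-cell correlation within a field is available.
5. **Cohort statistics.** Uncorrected Pearson χ² on 2×2 tables of
   dichotomized score vs. recurrence (the uncorrected statistic is what
   reproduces the published values; Yates' correction does not); empirical
   ROC with the cut-off maximizing sensitivity + specificity (Youden,
   ties to the smaller threshold, AUC by trapezoid = Mann–Whitney);
   Kaplan–Meier estimation and the Mantel–Cox log-rank test; Cox
   proportional-hazards fits (Efron ties, Wald inference) with
   removal-only backward elimination at p > 0.05. Published cut-offs ship
   as the `PAPER_CUTOFFS` preset (ENR 0.5, nuclear 48, total 72.5,
   extranuclear 28, PR H-score 100, ER H-score 110, ER Allred 6).

## Synthetic data: what it emulates and what it does not

`simulate_field` generates one stained field with full ground truth:

- **Geometry.** Non-overlapping elliptical nuclei (radius ~N(3.5, 0.5²) μm,
  axis ratio U(0.7, 1)) placed by rejection sampling, fully inside the
  field. Whole-cell territories are the pixels within a per-cell membrane
  offset (~N(4, 0.5²) μm, the calibrated regime) of their nucleus, with
  contested pixels going to the nearer nucleus — confluent epithelium
  rather than isolated cells, so territories truncate each other exactly
  as the nearest-neighbor rule assumes.
- **Particles.** Per-cell nuclear and extranuclear counts are negative
  binomial (default means 10 and 3, dispersion r = 5; variance
  m + m²/r — overdispersion is the realistic regime for per-cell particle
  counts; `dispersion=inf` recovers Poisson). Nuclear spots are uniform
  over the nucleus, extranuclear spots uniform over the nucleus–membrane
  annulus. A sparse rain of **stray** particles (0.01/μm² of stromal
  background, a few percent of specific signal) models nonspecific
  binding; it is what makes over-large acceptance distances measurably
  worse during calibration, as in the bench validation.
- **Rendering.** Spots are Gaussian puncta (σ = 0.3 μm, amplitude 300)
  over a flat background (100) with additive Gaussian noise (sd 5, a
  Gaussian stand-in for Poisson-dominated camera noise at these levels);
  default SNR ≈ 60.
- **Not emulated:** tissue autofluorescence texture, uneven illumination,
  optical sectioning/3-D, nucleus segmentation error, photobleaching, and
  spot-splitting of merged particles. A green calibration test therefore
  establishes that the assignment geometry and scoring are correct and
  that the distance sweep recovers a planted membrane offset under
  realistic counting noise — not that detection is robust to real tissue
  background.

`simulate_cohort` draws a binary high/low-ENR group (35/65 high),
exponential event times with hazard ratio 3.8 (the published multivariate
ENR effect) over a baseline anchored to the published low-ENR six-year
disease-free survival of 93.3%, a `censoring_rate` fraction of patients
independently censored before their event, and administrative censoring at
16 years. The published group-wise 6-DFS rates and the HR 3.8 are mutually
inconsistent under this two-group exponential model (they imply a marginal
HR ≈ 6); the generator plants the HR and anchors the baseline, so the
simulated high-ENR 6-DFS is ~77%, not 65.7%. Covariate columns other than
ENR are outcome-independent schema fillers.

## Numerical choices

- **Coordinates:** 0-based, x = column, y = row, pixel centers at integer
  coordinates; all thresholds compared in μm (pixel size is a required
  input; 0.1625 μm/px is the default for a 40× objective on a common CCD).
- **Distance ties:** the per-label EDT pass processes labels in increasing
  order with strict (1e-9) improvement, so exact ties resolve to the
  smaller label deterministically; the pass is cropped to padded bounding
  boxes and asserted equal to the global EDT.
- **Plateau maxima:** a connected plateau of equal filtered values yields
  its lexicographically smallest (y, x) pixel.
- **Compartment rule:** a spot's compartment is decided by its centroid
  pixel only (nearest-integer rounding); no area-overlap fractions.
- **Merged puncta** closer than the minimum separation count once
  (documented limitation; no deconvolution). In calibration this biases
  estimate and truth identically, since both are computed from the same
  detected spot set.
- **Degenerate inputs:** empty masks, constant correlation inputs, zero
  margins, single-class ROC labels, no-event Cox fits, and constant
  covariates raise `ValueError`; Cox non-convergence (e.g. complete
  separation) raises `SeparationError`; an all-censored cohort draw and
  a ≥1%-saturated image warn.

## Open design points resolved here

- The source is ambiguous about whether calibration correlates cells or
  samples; both are supported, defaulting to samples (matching a panel of
  samples spanning expression levels). With identical generative means in
  every sample the between-sample variance degenerates to counting noise
  and no distance reaches r² ≥ 0.91; the validation experiment therefore
  spans a 10-fold expression range across samples.
- Particles farther than `d_max` from every nucleus are discarded, not
  folded into the total score (switchable by raising `d_max`).
- The ROC threshold grid is midpoints between distinct scores plus ±∞;
  with all-equal scores the curve degenerates to AUC 0.5 and the optimal
  threshold is −∞ by the smaller-tie rule.
- Backward elimination is removal-only (the source does not state an entry
  criterion) and stops when one covariate remains.

## Limitations

2-D only; single detection scale; no membrane segmentation (whole-cell
masks are inputs); no spot-splitting; KM/log-rank/Cox assume independent
censoring and proportional hazards; the cohort generator is a schema-level
emulation, not a clinical data model.
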