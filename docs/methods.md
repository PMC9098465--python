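# Methods

This note documents the models, the synthetic data-generating process, and
the numerical and design choices behind `maltpred`.

## The prediction problem

Malting-quality (MQ) traits of spring barley — filtering speed (FS, cm/20
min), extract yield (EY, %), wort color (WC, EBC units), beta-glucan (BG,
mg/L) and wort viscosity (WV, mPa·s) — are expensive to measure. A 1H-NMR
spectrum of the wort, binned into thousands of intensity features along the
chemical-shift (ppm) axis, captures the metabolite profile of the same
material and can serve as an inexpensive proxy. The package asks: how much
of the phenotypic variance do the metabolomic features carry, and how well
can they predict the phenotype of unseen plots, unseen lines, and unseen
locations?

## Spectral preprocessing

The pipeline is `exclude → PQN → align → standardize`, in that fixed order:

1. **Region exclusion.** Bins below 0.70 ppm and above 9.00 ppm (no
   metabolite signal), the water resonance (4.7–4.9 ppm), and the chemical-
   shift reference standard (−0.2 to 0.2 ppm) are removed. Interval bounds
   are treated as *closed* so the retained-bin count is exactly
   reproducible. Exclusion runs first so solvent regions cannot distort the
   normalization quotients.
2. **Probabilistic quotient normalization (PQN).** Each spectrum is divided
   by the median of its bin-wise ratios to a reference spectrum,
   element-wise median across samples by default (the method's canonical
   reference), removing per-sample dilution. PQN is idempotent for a fixed
   reference.
3. **Interval alignment.** A deliberately simplified variant of interval
   correlation shifting (icoshift): within fixed, contiguous bin-index
   intervals (default length 200 bins), each sample segment is moved by the
   integer shift in ±`max_shift` bins that maximizes its inner product with
   the reference (median) segment. Integer shifts only, no interpolation;
   vacated edge positions take the segment's boundary value; ties break
   toward the smallest |shift|, then toward the negative shift. Variable
   segment optimization of full icoshift is deliberately out of scope.
4. **Standardization.** Every retained bin is centered and scaled to mean 0
   and standard deviation 1 using the **population (divisor n)** standard
   deviation. This convention is load-bearing: it makes the mean diagonal of
   the similarity matrix below equal 1 *exactly*, so the variance component
   attached to the kernel sits on the phenotypic scale. Zero-variance bins
   are dropped with a warning and recorded.

## The metabolomic kernel and mixed model

With Q the n × m standardized feature matrix, the metabolomic similarity
matrix is

    M = Q Q′ / m,

the same construction as a genomic relationship matrix from centered/scaled
markers (VanRaden's first method). An optional feature mask restricts the
columns (with the divisor equal to the masked count), supporting kernels
built from feature subsets; no re-centering happens inside the kernel —
Q's statistics live exclusively in preprocessing.

The mixed model per trait is

    y = 1μ + m + e,   m ~ N(0, M σ²ₘ),   e ~ N(0, I σ²ₑ),

with the intercept as the only fixed effect: the metabolome is measured on
the harvested material, so location and year effects are already expressed
in the spectra and absorbed by m. Total variance is σ²ₚ = M̄σ²ₘ + σ²ₑ
(M̄ = mean diagonal of M = 1 here), and the **relative variance
component**

    RVCm = M̄σ²ₘ / σ²ₚ

is the fraction of phenotypic variance carried by the metabolome.

### REML implementation

Implemented from first principles, not via a mixed-model library. M is
eigendecomposed once per dataset; the restricted likelihood is profiled
down to the single variance fraction h = RVCm, with the total variance
available in closed form at each h, and h is found by a 65-point grid scan
followed by bounded scalar minimization inside the best grid bracket
(absolute tolerance 1e-8 on h ∈ [1e-6, 1−1e-6]). The grid guard guarantees
the returned optimum is never beaten by a coarse scan; estimates landing at
a bound are flagged (`at_bound`), not treated as errors. The reported
standard error of RVCm is a profile-curvature approximation (numerical
second derivative of the restricted log-likelihood at the optimum) and is
labeled as such; it is not a REML information-matrix standard error.

### BLUP prediction and its oracle

Held-out plots are predicted by

    ŷ = μ̂ + M₍target,train₎ (M₍train,train₎ + λI)⁻¹ (y_train − 1μ̂),

with λ = σ̂²ₑ/σ̂²ₘ and μ̂ the GLS intercept on the training block (a 1e-10
diagonal jitter guards against exact singularity; σ̂²ₘ = 0 degenerates to
the constant μ̂). This is algebraically identical to ridge regression on
the columns of Q with penalty m·λ — the test suite exploits this duality
as the primary correctness oracle, comparing the kernel-form predictions
against an independent feature-space solve to 1e-8.

In cross-validation, variance components are re-estimated inside every
fold by default (`refit_per_fold=True`), re-decomposing the training
submatrix; reusing full-data estimates is supported and labeled in outputs.

## PLS1 regression

NIPALS with explicit deflation: w = X′y (normalized), t = Xw, p = X′t/t′t,
q = y′t/t′t, deflate X and y, repeat. Fitting centers X and y on *training*
means only — features are already scaled globally, so no per-fit
re-scaling — which keeps validation rows out of every training statistic.
The fitted model is folded into a single (coefficients, intercept) pair via
b = W(P′W)⁻¹q; the nested-model coefficient path is stored so one fit
serves all smaller component counts. A vanishing weight vector stops the
iteration early with a warning.

Component choice: an inner leave-one-sample-out (LOO) cross-validation over
the grid {5, 10, 20, 50} (arbitrary grids allowed), selecting the count
with the highest LOO correlation, ties toward fewer components. Both the
LOO-selected and fixed-count modes exist because it is genuinely ambiguous
whether inner tuning should pick the count or merely assess it; the outer
cross-validation drivers default to the **fixed 20-component mode** (the
count that dominates the component comparison) for runtime reasons — a
full inner LOO inside every outer fold multiplies cost by the training-set
size — and every output labels the mode used.

## Cross-validation designs

- **SIZE** — training sets of fixed size drawn uniformly without
  replacement; the validation set is the complement. Replicated draws
  (default 15); accuracy computed per replicate and summarized as mean and
  sample standard deviation (the "±" in all outputs is the sd across
  replicates, labeled `sd`).
- **LINE** — one fold per line, holding out all of its plots: prediction of
  an unseen genotype.
- **LOC** — one fold per location: prediction of an unseen environment.

For LINE and LOC, per-fold predictions are pooled — every plot predicted
exactly once — before correlating (plot level), and per-line averages of
observed and predicted values are correlated for the line-mean accuracy.
Accuracy is always the Pearson correlation; zero-variance cases return a
flagged missing value. Replicate seeds derive deterministically from
(base seed, replicate index) so any replicate is reproducible in
isolation. A predictor failure marks the fold failed and the run
continues. Both predictor families receive identical fold partitions.

## The synthetic generator

The generator emulates the structure of a two-location, three-year barley
trial. Defaults are desk-scale: 150 lines × 2 locations × 2 replicates =
600 plots, 2000 bins over 0–11 ppm, 40 metabolites. Lines are partitioned
over years in near-equal chunks (most breeding lines appear in a single
season); within each location × year, lines are chunked into trials of 25
(trial *effects* are omitted by default, matching the mixed model above,
but `trial_effect_sd` can add them for robustness studies).

Data-generating chain, with all latent quantities stored losslessly:

- **Concentrations** c_ik = base_k + line + location + year + plot noise
  (normal effects; defaults 1.0 / 0.3 / 0.3 / 0.5 on a base of U(2, 8)),
  clipped at zero.
- **Spectra**: each metabolite contributes 1–3 Lorentzian peaks
  (half-width 0.008–0.025 ppm, centers clear of the excluded regions);
  clean spectrum = concentration-weighted sum of profiles; observed =
  dilution × integer-shifted clean + bin noise. Dilutions are log-normal
  with median 1 (sd 0.15 on the log scale — PQN's canonical use case);
  whole-spectrum shifts are uniform integers in ±3 bins; bin noise sd 0.02
  (high signal-to-noise, as in real 1D 1H NMR).
- **Phenotypes**: y = μ + m + e with m = Σ_k β_k c_ik (centered), i.e.
  linear in *true* concentrations, not observed bins — preprocessing
  quality therefore genuinely affects attainable accuracy. The effect
  vector β is drawn once per trait and rescaled so the realized var(m)
  equals RVCm_target × sd_trait²; the residual sd is then solved
  analytically so the realized metabolomic variance fraction hits the
  target in expectation (which makes parameter-recovery tests sharp).
  Per-trait intercepts, total sds and targets default to FS (4.83, 0.61,
  0.93), EY (82.66, 1.82, 0.94), WC (5.83, 0.83, 0.97), BG (217.10,
  115.23, 0.98), WV (1.47, 0.06, 0.97).

Identical config + seed reproduces a dataset bit for bit; the bin grid is
rejected if coarser than the narrowest peak's full width; ppm axes are
rounded to 4 decimals at construction so on-disk serialization is exact.

**What the generator does not emulate:** raw FID processing (apodization,
Fourier transform, phasing, baseline correction), peak-shape distortions,
correlated baseline artifacts, genotypes/pedigree, trait-specific
metabolite biology (each trait loads on all metabolites with random
signs), or unbalanced trial capacities. Passing tests therefore show the
*methods* behave correctly under the stated generative assumptions, not
that field data would reach the same accuracies; because the synthetic
phenotype is exactly linear in concentrations and the kernel sees noisy
linear images of those concentrations, desk-scale accuracies run higher
than field results, while the qualitative patterns (accuracy rising with
training size, kernel BLUP overtaking PLS beyond small training sets,
mid-grid component counts beating 50, LINE/LOC below SIZE at comparable
training sizes) are the meaningful outcomes.

## Problem sizes used by the shipped analyses

The numbered drivers and the acceptance script run the 600-plot / 2000-bin
default (≈1472 retained features), SIZE at 50–400 training plots, LINE
over 150 lines, LOC over 2 locations — the package's chosen desk scale.
The study-scale design (564 lines, 2667 plots, 24,018 bins) is reachable
through `SimulationConfig` but is not a default.

## Numerical choices and degenerate inputs

- Variance-fraction bounds [1e-6, 1−1e-6]; optimizer tolerance 1e-8;
  kernel PSD tolerance: smallest eigenvalue ≥ −1e-8 × largest.
- Standardization drops zero-variance bins (warning + record); samples
  with all-zero intensities make PQN fail loudly with the plot id.
- Alignment requires every interval ≥ 2·max_shift+1 bins.
- PLS component counts are capped at min(n−1, m); LOO tuning skips grid
  values above n−2 with a warning and refuses n < 5.
- Accuracy functions return NaN (not an exception) for zero-variance
  inputs and fewer than 3 lines; replicate summaries with one replicate
  report the mean with the spread flagged missing.
- Tables are tab-delimited UTF-8, '.' decimal; doubles serialized at full
  round-trip precision, ppm headers at 4 decimals.

## Known limitations

- The simplified aligner uses fixed intervals and integer shifts; spectra
  with large or sub-bin misalignments need real icoshift upstream.
- REML standard errors are curvature approximations; no sampling-based
  uncertainty for accuracies beyond the replicate sd.
- Single-kernel models only: no multi-kernel combinations, no genomic
  relationship matrices, no additional fixed or random effects.
- Across-year cross-validation is not implemented (the emulated design has
  almost no line overlap between years, which would confound it).
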