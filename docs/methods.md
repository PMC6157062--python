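# Methods

`lignomap` implements a quantitative chemical-imaging workflow for plant
cell-wall biomass: calibrate concentration models for cellulose,
hemicellulose, and lignin on bulk (macro) FTIR spectra of powdered samples,
transfer the calibration to a micro-FTIR imaging instrument by direct
standardization, and predict the three mass fractions at every pixel of a
tissue-section hypercube.  This note records the models, the defaults and
why they are what they are, what the synthetic data generator does and does
not emulate, and the numerical choices made where the design was open.

## Spectra and grids

All spectra live on strictly ascending wavenumber grids (cm⁻¹) and all
modelling is done in absorbance, where Beer–Lambert mixing is linear;
transmittance input is converted at load (`A = −log₁₀ T`).  Two fixed axes
matter:

* **Common grid** — 2800 evenly spaced points on 675–4000 cm⁻¹ inclusive
  (step ≈ 1.188 cm⁻¹).  This is the shared master/slave axis used for
  calibration transfer: the macro instrument's wider range is trimmed to
  the micro instrument's 675–4000 cm⁻¹ window and both sides are
  spline-resampled onto it.
* **Effective range** — 881–3581 cm⁻¹ (2273 of the 2800 points).  FTIR
  noise dominates near the range edges, so models are trained only on this
  closed interval.  Model band indices are stored relative to the *input*
  grid, so a model trained on effective-range (or CARS-selected) bands
  applies index-for-index to transfer-corrected pixels on the common grid.

Resampling uses a natural cubic spline and refuses to extrapolate.  Natural
boundary conditions are deliberately conservative: they leave a small O(1e-4)
artifact within a few points of the range edges (the interior is accurate to
~1e-7 for band-limited signals), which is acceptable because the effective
range discards the edges anyway.

## PLS1 calibration

One model per component (PLS1), fitted by NIPALS with deflation of X only on
mean-centred data; prediction is `(x − x̄)·b + ȳ`.  Coefficients for every
latent-variable (LV) count up to A come from a single decomposition, which
makes the RMSECV-vs-LV curve cheap — important because the outlier screen
and the band-selection search run thousands of fits.  The implementation is
checked in the tests against two independent routes: the least-squares
solution at `n_lv = p`, and scikit-learn's `PLSRegression`.

Cross-validation is 5-fold with fold assignment by seeded shuffle, held
identical across every candidate (LV counts, interval combinations, CARS
subsets) within one selection run so RMSECV values compare like-for-like.
The LV count is the argmin of the RMSECV curve (first minimum on ties),
capped at 20 for final models and 15 inside selection runs.  R² is reported
as the squared Pearson correlation (chemometric convention, separately for
calibration and prediction sets); RPD is the prediction-set reference STD
divided by RMSEP.

## Sample allocation and outlier screening

**Allocation.**  Samples are sorted ascending by the component's reference
value, cut into consecutive triples, and the middle-ranked member of each
complete triple goes to the prediction set (trailing partial groups stay in
calibration).  The extremes of every triple remain in calibration, so the
calibration range always covers the prediction range; 180 samples give
120/60.  Ties break by (value, original index) for determinism.

**Monte-Carlo screening.**  Over `n_loops` (default 5000) random 4:1
calibration/validation splits, a PLS1 model is fitted on the 80% and each
validation sample's residual recorded; the per-sample mean and STD of these
residuals over its validation appearances summarize its compatibility with
models built from the rest.  The screening LV count is fixed once, by
cross-validation on the full data.  Because the published procedure reads
the mean-vs-STD scatter by eye, the automated cut is robust: flag when the
mean deviates from the cohort median by more than 3 × (1.4826·MAD), or the
STD exceeds the median STD by the same one-sided criterion.  A numerical
floor (1e-10 of the response STD) prevents machine-epsilon scatter from
flagging on noise-free data.

A known property of this rule: residual means are leverage-structured
(samples at the edge of concentration space carry larger model bias), so on
*uniformly* distributed concentrations their distribution is heavy-tailed
(kurtosis 6–9) and the Gaussian-calibrated 3σ cut flags ~4% of clean
samples.  Under the factorial design's truncated-normal concentrations the
clean false-flag rate is ~1.3%, and a +10·STD planted response outlier is
flagged essentially always.  Studentized alternatives are out of scope.

## Two-stage band selection

**iPLS.**  The effective range is cut into equidistant windows of 99
variables (the last may be short); a cross-validated PLS1 model is scored on
each window; then a greedy forward search over window combinations — seeded
at the best single window, adding whichever window most reduces RMSECV,
stopping at no improvement — returns the winning region set.  Greedy forward
search was chosen over exhaustive 2^k enumeration; the combination's RMSECV
is never worse than the best single window's by construction.

**CARS.**  Within the iPLS region, N = 50 iterations of competitive
adaptive reweighted sampling: each iteration (i) draws 80% of the
calibration samples, (ii) fits PLS1 with an inner-CV-chosen LV count and
normalizes |coefficients| into weights, (iii) enforces the exponentially
decaying retention ratio `r_i = a·e^(−k·i)` pinned to `r_1 = 1` and
`r_N = 2/p` (keeping the largest-weight bands), (iv) resamples the
survivors with probability proportional to weight (p draws with
replacement, so the retained count tracks the decay schedule while weak
bands drop out stochastically), and (v) records the subset's 5-fold RMSECV.
The subset with the global minimum RMSECV wins; retention counts are
non-increasing.  Two details matter in practice and were settled by
measurement against synthetic data with known informative bands: the weight
fit must use the inner-CV LV count (weights at an over-large fixed LV are
noise-dominated and selection loses focus), and the resampling draw count
must not shrink the subset faster than the decay schedule.

Selection runs per component (three independent CARS runs).  On the
synthetic study conditions the two stages together retain 0.3–4.2% of the
2273 effective-range variables (seeds 1–7), comfortably under the 5%
headline reduction.

## Direct standardization

The transfer solves `X_master = X_slave · E + B` on representative standard
pairs: the mean macro spectrum of each growth site's samples on the master
side, and the all-pixel mean of that site's tissue hypercube on the slave
side.  Both sides are mean-centred; E is the minimal-norm least-squares
solution via a truncated-SVD pseudoinverse (relative cutoff 1e-8); B absorbs
the means.  With three standards the centred system has rank ≤ 2, so E is a
heavily rank-deficient projection: it reproduces the standards exactly and
maps anything orthogonal to their span to the master mean.  Consequences
worth stating plainly:

* spectral (hence concentration) variation outside the span of the
  site-mean differences cannot survive the transfer — pixelwise recovery of
  three components through a rank-2 map is only well-posed because tissue
  variation is dominated by one axis (fiber-strand vs parenchyma
  composition) that the site means also express;
* the standards must be *representative*: master and slave sides must
  describe the same material.  The synthetic pipeline enforces this by
  pinning each generated cube's mean composition to the realized macro site
  mean;
* path-length differences between KBr pellets and 15 μm sections are
  absorbed implicitly by E's scaling; no explicit normalization is applied.

Piecewise DS and slope/bias correction are out of scope.

## Imaging

`predict_map` applies the transfer pixelwise, restricts to the model's band
indices, and predicts; out-of-gamut fractions (<0 or >1) are reported via a
validity mask, never clipped — clipping would hide transfer failure.
`single_band_map` renders the classical semi-quantitative comparison: the
absorbance image at one assignment wavenumber (1157 cm⁻¹ carbohydrate
C–O–C, 1504 cm⁻¹ lignin aromatic skeleton, 1734 cm⁻¹ ester C=O), looked up
nearest-neighbour within two grid steps, ties to the lower index.  Maps are
persisted as CSV plus a deterministic pseudo-colour PNG with recorded
colour bounds.

## Synthetic data: what is emulated, and what is not

No public dataset accompanies this problem, so the generator is first-class
code and defines the study conditions end to end.

**Design** (`gen_design`): 3 sites × 5 ages × 4 parts × 3 replicates = 180
samples.  Component mass fractions are truncated-normal around cellulose
0.446 ± 0.029, hemicellulose 0.237 ± 0.025, lignin 0.204 ± 0.019, plus
small zero-sum effects whose signs follow the field observations (1-year
culms: more cellulose, less hemicellulose/lignin; nodes: the reverse;
cellulose DSH > BT > MY; hemicellulose lowest at DSH).  Site effects are
tied to each site's tissue strand fraction (below) so the macro cohort and
the imaged sections describe one consistent population.  Rows are rescaled
if the three fractions would sum past 0.95; the remainder is
non-lignocellulosic residue.

**Pure spectra** (`gen_pure_spectra`): sums of Gaussian bands at literature
assignment positions, 12 cm⁻¹ FWHM in the fingerprint (180 cm⁻¹ for the
broad O–H envelope at 3449, 60 cm⁻¹ for C–H at 2946) — widths chosen to
resemble real lignocellulose absorbance profiles, since only centers are
tabulated.  The overlaps that defeat single-band imaging are built in:
shared carbohydrate bands at 1157/1369/1415/1430/1457, the 1610 band shared
by all three polymers, and the ester 1734 band carried by hemicellulose
(0.9) with a substantial lignin contribution (0.45) — sized so the 1734
image tracks hemicellulose + lignin rather than either alone, as observed.
A featureless residue spectrum carries the non-lignocellulose mass.

**Macro spectra** (`gen_macro_spectra`): Beer–Lambert mixing plus a shared
linear baseline, i.i.d. detector noise scaled to a target SNR
(mean-signal / noise-SD; default 200), per-sample pellet path-length gain
jitter (SD 1.5%) and baseline offset jitter (SD 0.004), and wet-chemistry
assay error on the *reported* reference values (SD 0.004 absolute).  The
assay error sets the realistic floor on RMSEP (≈0.004, i.e. R²p ≈ 0.96–0.98
at these STDs); without it the exactly low-rank mixture is recovered to
numerical precision and error ratios against RMSEP become meaningless.

**Slave response** (`gen_slave`): Gaussian broadening from the master's
4 cm⁻¹ resolution to the slave's 8 cm⁻¹, a 2 cm⁻¹ registration shift
(spline resampling, edge values held over the boundary sliver), gain 0.8,
offset 0.02, extra noise SD 0.002.

**Tissue cubes** (`gen_hypercube`): 21 × 21 pixels at 10 μm (the 210 μm
field), a central fiber-strand disk with a sigmoidal transition band
(width 1.5 px) inside parenchyma.  Strand-minus-parenchyma contrast is
(+0.10, −0.03, +0.07) for (cellulose, hemicellulose, lignin) — thick-walled
fibers rich in cellulose and lignin, hemicellulose mildly depleted, i.e.
relatively uniform.  Site strand-area fractions are 0.25/0.45/0.65
(MY/BT/DSH); per-pixel concentration jitter SD 0.006 emulates within-section
heterogeneity.  When a macro dataset is supplied, each cube's mean
composition is pinned to the realized macro site mean — the sections are
cut from the same collected culms as the powder, which is what makes the
site means valid transfer standards.

**Not emulated:** radiative transfer and Mie scattering, atmospheric CO₂
artifact bands, detector nonlinearity, per-pixel section-thickness
variation, and spatial correlation of pixel noise.  Passing tests therefore
demonstrate the pipeline's correctness and its statistical behaviour under
linear mixing with realistic noise and instrument mismatch — not robustness
to scattering artifacts or to non-representative standards, which on real
data must be checked with the out-of-gamut diagnostics the maps carry.

## Numerical choices and degenerate inputs

* Grids are strictly increasing and positive; duplicate wavenumbers are an
  error, as are range selections retaining fewer than two points.
* PLS deflation stops early (coefficients frozen) if X deflates to zero;
  requested LV counts above feasibility are reduced with a warning.
* The DS SVD cutoff is relative (1e-8 × σ_max); representative sets with
  non-finite values are rejected.
* CARS subsets smaller than the LV count are skipped with a warning (once
  per run); the EDF endpoints follow `r_1 = 1`, `r_N = 2/p` exactly.
* All randomness flows from `numpy.random.default_rng` seeds; the pipeline
  fans one global seed into stage seeds via `(seed·1009 + k) mod 2³¹`, and
  replaying a recipe on identical inputs reproduces identical artifacts.

## Problem sizes used in the test suite

The suite exercises the full 2800-point common grid and the 180-sample
design where the claims concern them (allocation arithmetic, effective
range, end-to-end recovery) and a 600-point 900–1800 cm⁻¹ fingerprint grid
with 24–36-sample designs for unit-level checks.  Stochastic guarantees are
asserted as majorities over a 10-seed panel (prediction R², pixel recovery,
transfer benefit) or the full 20 seeds at 1000 Monte-Carlo loops (outlier
screen), with measured per-seed pass rates of 8–10/10.
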