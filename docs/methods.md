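# Methods

## The question the package operationalises

PCR builds its latent components from the spectral matrix X alone; PLS1
tilts each component toward the X–y covariance. The package quantifies the
interpretive cost of that tilt: how far the peaks of the interpretable curve
(PCR: the loading of the most response-relevant component; PLS: the full
regression-coefficient vector b) sit from the literature band assignments
BA_L of each constituent. The elementary datum is the residual
R = C − BA_L (cm⁻¹), pooled per method across constituents and
pretreatments; accuracy is judged by the 95% interval on mean R covering
zero, precision by a one-tailed variance F-test between methods.

## Synthetic data model

Real hardwood FT-NIR calibration sets of this design were never deposited,
so the generator produces surrogates with the structure the analysis needs:

* **Grid** — 10,000–4,000 cm⁻¹ at 4 cm⁻¹ (1,501 points), stored ascending;
  files in descending instrument order are normalized on read.
* **Chemistry** — per-sample constituent fractions drawn uniformly from
  hardwood-plausible windows (extractives 1–8, lignin 18–30, cellulose
  38–52, hemicellulose 15–30 % w/w), redrawn per sample until the four sum
  to ≤ 100. These windows are a declared design choice: no concentration
  distributions were published for the original samples, and the chosen
  spans give response variances on the scale wood-chemistry RMSEPs are
  reported at (≈ 1–3 % w/w).
* **Spectra** — Beer–Lambert mixtures of Gaussian bands centred at the
  packaged literature assignments: lignin 4401, 4411, 4280; extractives
  6913, 7092; cellulose 6307, 5814, 4405; hemicellulose 7410, 6003, 5236,
  4686 cm⁻¹. Band shape is Gaussian with an 80 cm⁻¹ sd default — broad NIR
  overtone/combination bands; only peak positions are literature-given, so
  width and amplitude are generator parameters, not claims about wood.
* **Artefacts** — per-sample multiplicative path-length factor
  1 + N(0, 0.05); additive baseline offset N(0, 0.02 AU) and slope
  N(0, 1e-5 AU/cm⁻¹) (≈ ±0.06 AU tilt across the range — the
  density/scattering baseline shift that motivates derivative
  pretreatment); white noise N(0, 0.001 AU) per point, the magnitude of a
  well-averaged FT-NIR scan; duplicate-assay error N(0, 0.5 % w/w) on the
  reference chemistry, truncated at zero.

Everything is reproducible from a single seed; the pipeline derives
independent per-stage and per-replicate substreams, so adding replicates
never perturbs earlier ones.

What the generator does **not** emulate: instrument line shape and
interferogram processing, moisture/temperature drift, the dense multiplet
structure of real NIR spectra (each constituent absorbs at many more
wavenumbers than its tabulated assignments), nonlinear scatter, and
between-genus covariance among constituents. Passing tests therefore
demonstrate correctness of the machinery and behaviour under the stated
error model — not that real wood spectra would yield the same variance
ordering.

## Preprocessing

Savitzky-Golay first derivative: 2nd-order local polynomial, 25-point
window, derivative expressed per cm⁻¹ (divided by the grid step) so peak
positions are grid-invariant. The 12 edge points per side are trimmed rather
than padded — padded boundary values could masquerade as loading peaks.
"25 points" is read as the full convolution window, the usual convention.
No smoothing is applied to raw spectra, and no other pretreatment (SNV,
MSC, second derivative) is implemented.

## Chemometrics

Both engines center X and y (no unit-variance scaling — standard for
spectra, and required if loading shapes are to be read as absorbance
patterns). PCR takes components from the SVD of centered X, with each
loading's sign fixed so its largest-|element| is positive (deterministic
decomposition; fitted values are invariant to the convention). y is then
regressed on the k scores; the "most significant PC" is the score with the
largest |t| in that regression (two-sided t, ties to the lower index).
PLS1 is NIPALS: w_j ∝ X_jᵀy_j, deflation X_{j+1} = X_j − t_j p_jᵀ,
b = W(PᵀW)⁻¹q; deterministic for a single response. At k = rank(X) both
engines coincide with the minimum-norm least-squares solution, which the
tests use as an independent oracle (scikit-learn's NIPALS is a second
cross-check, never the implementation).

Component counts default to leave-one-out cross-validation with a parsimony
rule: the smallest k whose RMSECV is within 2% of the global minimum,
capped at min(10, n − 2). A 31/6 holdout split is available behind a flag;
candidate splits are redrawn (up to 100 times) until calibration and
validation means differ by < 0.5 pooled sd per constituent. Diagnostics:
r² as squared Pearson correlation × 100, RMSE with an n denominator,
RPD = sd(y_ref, n−1)/RMSEP (infinite sentinel at zero RMSEP).

## Peaks and matching

Peaks are grid-point local extrema of the profile in both polarities — no
sub-grid interpolation, keeping C on the 4 cm⁻¹ lattice a plot reader would
use. A peak is kept when its prominence reaches 10% of the global |c|
maximum (default): small enough to retain genuine secondary loadings, large
enough to suppress noise wiggles; the detector is scale-invariant by
construction. Matching to assignments is greedy nearest-first within
±60 cm⁻¹ (wide enough for the observed 20–30 cm⁻¹ derivative shifts, narrow
enough to avoid cross-band capture), each peak and each assignment used at
most once; distance ties resolve toward the lower assignment wavenumber.
Unmatched assignments stay in the table flagged, but are excluded from the
residual pool rather than imputed.

## Precision statistics

The per-method interval on mean R uses the t distribution with n − 1 df;
with 15 observations this reproduces published half-widths (7.6 and
14.7 cm⁻¹ from variances 189 and 700) that a z interval does not (6.9 and
13.4). The F statistic is oriented PCR-variance over PLS-variance with the
*lower*-tail probability P(F ≤ f) reported — the convention under which the
printed pair (F = 0.27, p = 0.0099) is coherent — rather than the textbook
larger-over-smaller orientation. Normality of R is not tested; when a
pool's |skewness| exceeds 1 the report carries a caution note instead.

## Problem sizes and numerical choices

Default study: 37 samples × 1,501 wavenumbers, 4 constituents × 2 methods
× 2 pretreatments = 16 model cells, LOO (37 refits) per cell; one study
runs in ≈ 1.5 s, so the Monte-Carlo mode defaults to 50 replicates and the
verification runs use 30. The peak-recovery noise sweep uses a single-band
system (one constituent, band at 6,000 cm⁻¹) at additive-noise levels
0.002, 0.01 and 0.05 AU — spanning from near-noiseless to clearly degraded
relative to the ≈ 0.05 AU signal variation of that system — with 30
seeded replicates per level. Rank decisions use a relative singular-value
threshold of 1e-10; matrices are never explicitly inverted except the k×k
PᵀW solve in PLS.

## Known limitations

* Pooled residual counts vary by realisation (unmatched assignments are
  dropped), so the per-method df differs between replicates — as it would
  between real studies.
* High-component PLS fits on derivative spectra can produce very wiggly
  coefficient vectors; with a global prominence threshold this yields many
  detected peaks, of which only the band-window matches enter the pool.
  A per-region threshold would be a natural extension.
* The one-tailed F-test inherits its sensitivity to non-normal R from the
  classical variance-ratio test; Levene/Brown–Forsythe alternatives are
  documented extensions, not implemented.
* The directional Monte-Carlo summary (fraction of replicates with
  var(R_PLS) ≥ var(R_PCR)) is a description of behaviour under the
  synthetic error model, not a reproduction of any particular observed
  dataset's outcome.
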