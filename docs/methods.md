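# Methods

## The measurement model

A centroided MSI dataset is a grid of peak lists, one per pixel
(`SpectrumGrid`), at a default pitch of 150 × 500 µm (lateral scan ×
line step of an airflow-assisted DESI stage). Ion images are extracted by
summing peak intensities inside a relative mass window
|m/z − target| / target ≤ tol × 10⁻⁶. Summation (not maximum) is the
default aggregation because it is linear in peak intensity, and the whole
calibration chain below relies on that linearity. The window half-width
defaults to 10 ppm — Orbitrap-class accuracy at m/z ≈ 900 — and is
configurable everywhere; no TIC or RMS normalization is applied by default.

The working model for the drug channel at pixel *p* is

    I(p) = S · m(t(p)) · C(p) · ε(p),

with S an unknown instrument sensitivity (counts per pmol/mm²),
m(t) ∈ (0, 1] the tissue-specific **matrix factor** of the tissue at *p*,
C(p) the areal concentration (pmol/mm²) and ε multiplicative lognormal
noise. Because S and m are unknown and m varies ~5-fold between tissues,
raw intensity cannot be compared across organs.

## Virtual calibration

**Relative calibration factors.** On an equal-concentration mimetic model
(every tissue type spotted with the same amount), the tissue means of the
drug image estimate m(t) up to a constant. The RCF table divides each
tissue mean by the pooled pixel mean, so the pixel-count-weighted grand
mean of the table is exactly 1. This grand-mean convention avoids naming an
arbitrary reference organ; any constant convention cancels later because
the standard curve is calibrated with the same factors.

**Natural internal standards.** Feature channels are screened by Pearson
correlation with the drug image *across the pixels of the
equal-concentration model*, where intensity variation reflects matrix
effect rather than dose; features with r strictly above 0.4 are kept.
Constant channels are undefined and never selected. Screening on dosed
tissue instead would confound dose with matrix effect.

**RCF regression.** A single hidden layer of 10 tanh units with a linear
output maps the selected (z-scored) features to per-pixel RCF. Training
minimizes MSE with the Levenberg–Marquardt algorithm (MINPACK `lmder`
through `scipy.optimize.least_squares`, analytic Jacobian), run in stages
of 25 function evaluations; after each stage the validation MSE is checked
and the best weights kept, stopping after 6 checks without improvement or
a 1000-evaluation budget. Pixels are split 70/15/15 (train/validation/test)
by a seeded uniform permutation with floor counts and remainder assigned
train-first. Predictions are clipped to [0.05, 20] so the subsequent
division cannot blow up; the worst-case distortion this admits (400-fold)
is far outside any physical matrix effect. When the training target is
constant the trainer warns and returns a constant model.

**Calibration and quantitation.** Each drug pixel is divided by its
predicted RCF; a standard curve is then fitted by unweighted OLS (free
intercept) of calibrated spot-mean intensity on spiked concentration using
the dilution-series mimetic model. The curve's Pearson r is reported on
the (concentration, spot mean) pairs — the convention under which a
calibration curve's linearity is normally quoted — because single-pixel
multiplicative noise bounds the pooled per-pixel r away from 1 (≈ 0.98 at
σ = 0.15 even for perfect calibration); the pooled per-pixel r is exposed
as a separate diagnostic. Inverting the curve gives pmol/mm² per pixel;
negative values are clamped to 0 and counted in the map's provenance.

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes,
with per-pixel ground truth (concentration, matrix factor, labels):

* **Geometry.** 60 × 120 grid; 8 regions (heart, liver, spleen, lung,
  kidney, brain, muscle, tumor) as axis-aligned ellipses/rectangles with
  areas within ~5× of one another, so every organ supports stable
  statistics at desk scale.
* **Matrix factors.** Defaults span 0.2–1.0 (5-fold) and are deliberately
  non-monotone in organ order. The true per-tissue magnitudes are not
  published for any real system; these are design choices, not fits.
* **Endogenous panel.** 20 channels at metabolite-range m/z. Ten *matrix*
  features have per-organ means proportional to the matrix factor; their
  within-organ lognormal noise is solved in closed form so the pixelwise
  Pearson correlation with the matrix-factor map equals the target
  (default 0.7). Ten *marker* features draw independent per-organ means
  with log-SD 1.0 (typically 3–10-fold between organs) and CV 0.25 —
  emulating tissue-specific metabolites that outline organs. Markers are
  uncorrelated with the matrix effect by construction and act as screening
  distractors, while carrying the organ identity that makes metabolite-
  profile segmentation possible.
* **Noise.** Multiplicative lognormal (σ = 0.15) on the drug channel, a
  uniform additive floor (5 counts) on every channel, and 1.5 ppm centroid
  mass jitter.
* **Mimetic models.** Spots of radius 3 px on an 8-px lattice. The
  equal-concentration variant spots every tissue 8 times at 8.9 pmol/mm²;
  the dilution variant spots **every level of the 8-point series
  (0.89–71.2 pmol/mm²) in every tissue type**, so the pooled uncalibrated
  curve mixes the full matrix spread at each level and the calibration
  benefit is a stable population quantity rather than an artifact of one
  concentration-to-tissue assignment.
* **Time courses.** One phantom per time point (default 0.5/3/11/24 h)
  with mono-exponential per-organ decay and fresh derived seeds.

What the phantom does **not** model: desorption/ionization physics,
isotope patterns, peak shape and interferences, spatial intensity
gradients within an organ, section-thickness variation, or chemical
identity of the endogenous features (they are generic m/z channels).
Passing the synthetic benchmark therefore shows the *pipeline logic* is
sound under the stated noise model — not that any particular real tissue
panel will support an r = 0.7 regression.

## Segmentation

Pixels are embedded with t-SNE (perplexity 30, PCA init, fixed seed) on
z-scored profiles and clustered with k-means (k-means++, 10 restarts, best
inertia). k defaults to the number of expected regions (+1 when the mask
retains background). Agreement with ground truth is scored with the
adjusted Rand index over co-labeled pixels. Clustering on the 2-D
embedding, rather than on raw profiles, is the deliberate choice: on the
default phantom it is markedly more robust to the region-size imbalance
that makes raw-space k-means split large regions.

## PK statistics

AUC uses the linear trapezoid over the observed span only — with four time
points, extrapolation to infinity is not defensible. Targeting efficiency
is the tumor's share of summed organ AUCs, `TE = AUC_tumor / Σ AUC`; the
organ set enters the denominator explicitly and must be reported alongside
RTE for the ratio to be reproducible. Group comparisons are classical
two-tailed Student's t-tests (pooled-variance unpaired or paired), with
star bands at p < 0.05/0.01/0.001 and mean ± SEM summaries. Masses come
from standard monoisotopic atomic masses with electron-mass correction for
ions; equimolar doses scale by the molar-mass ratio and are reported to
one decimal, per dosing convention.

## Numerical and degenerate-input choices

* ppm windows are closed intervals; peaks exactly on the boundary count.
* Pixels with no in-window peak yield 0, not NaN.
* Empty regions appear in summaries with n = 0 and NaN mean, never
  silently dropped; SEM is NaN for n ≤ 1.
* A tissue with zero mean drug intensity aborts the RCF table with the
  tissue named.
* The background mask keeps occupied pixels above the 5% TIC quantile by
  default; on phantoms with a noise floor this retains background pixels,
  which then form their own cluster (hence k + 1 in the pipeline).
* imzML serialization uses processed mode via pyimzml; peakless or
  all-zero spectra denote unoccupied pixels. Pixel pitch is not stored in
  the file and is re-supplied on read.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds stay below 2³¹. Re-running any stage with the same
  seeds reproduces results bit-for-bit within a process.

## Problem sizes

Default runs are desk-scale by design: 7,200-pixel phantoms, ~1,850-pixel
mimetic models, 20-feature panels, ~200 LM function evaluations. These
sizes keep a full pipeline run (including t-SNE) around a minute on one
CPU while leaving every per-organ statistic with ≥ 150 pixels.

## Known limitations

* The RCF network is a point estimator; no uncertainty is propagated into
  the concentration maps.
* The equal-concentration model must contain every tissue type expected in
  the dosed section; tissues absent from training are extrapolated by the
  clipped network without warning.
* Limit-of-detection/quantification estimation, ng/g conversion (needs
  density/thickness), profile-mode spectra and 3-D MSI are out of scope.
* With no detectable matrix effect (uniform matrix factors) the screen
  selects nothing; the pipeline treats this as a hard error, while the
  benchmark falls back to identity calibration — there is nothing to
  correct, and the two curves then agree.
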