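# vcqmsi — virtual-calibration quantitative mass spectrometry imaging

Mass spectrometry imaging (MSI) measures a drug's ion intensity in every
pixel of a tissue section, but raw intensity is a poor proxy for
concentration: each tissue suppresses or enhances ionization differently
(the *matrix effect*), so the same amount of drug can look five times
brighter in heart than in liver. The classical fix — spiking a
stable-isotope-labelled internal standard into every pixel — is costly and
impossible for early-stage candidate screens.

`vcqmsi` implements the *virtual calibration* alternative for
label-free absolute quantitation, aimed at DMPK and imaging scientists:

1. **Natural internal standards.** Endogenous metabolite channels whose
   intensities track the local matrix effect are selected by Pearson
   correlation with the drug signal (r > 0.4) on an *equal-concentration
   mimetic tissue model* — spotted arrays of drug standard in tissue
   homogenates of different organs.
2. **Relative calibration factors (RCF).** At equal spiked amount, each
   tissue's mean drug response relative to the grand mean defines its RCF.
   A single-hidden-layer neural network (10 tanh units, trained with
   Levenberg–Marquardt on a 70/15/15 pixel split with validation early
   stopping) regresses per-pixel RCF on the selected endogenous features.
3. **Pixel-wise calibration.** `I_cal(p) = I(p) / RCF_pred(p)` removes the
   matrix effect; an ordinary-least-squares standard curve fitted on a
   dilution-series mimetic model (8 levels, 0.89–71.2 pmol/mm²) converts
   calibrated intensity to areal concentration in pmol/mm².
4. **Downstream analysis.** t-SNE + k-means segmentation recognizes organs
   from metabolite profiles without manual ROIs; per-organ time courses
   reduce to trapezoidal AUC, targeting efficiency
   `TE = AUC_tumor / Σ AUC_organ`, and relative targeting efficiency
   `RTE = TE_test / TE_ref`.

Because no public MSI dataset accompanies the method, the package ships a
first-class synthetic-data module: whole-body phantoms with 8 labeled
organs, tissue-specific matrix factors spanning 5-fold, endogenous panels
with controlled feature–matrix-factor correlation, mimetic spot models, and
time-course series — all with per-pixel ground truth, so every stage is
testable against known answers.

## Worked example

`python examples/03_virtual_calibration.py` runs the core workflow on the
default synthetic mimetic models and prints:

```
features selected (r > 0.4): 12 / 20
RCF regression held-out R^2: 0.957
standard-curve Pearson r:    0.844 uncalibrated
                             0.998 calibrated
pooled per-pixel r:          0.831 -> 0.970
median |rel. error| of recovered concentration: 11.8% over 1856 pixels
```

Reading these numbers: the screen keeps the 10 matrix-tracking features
(plus 2 tissue markers that happen to correlate); the network explains 96%
of held-out RCF variance; the uncalibrated standard curve pools a 5-fold
tissue-response spread and is visibly non-linear (r = 0.844), while after
dividing by predicted RCF a single pooled curve is essentially exact
(r = 0.998); inverting that curve recovers per-pixel concentration to
~12% median error at 15% multiplicative measurement noise.

Other examples: `01_adduct_and_dose.py` (quantitative-ion m/z and
equimolar prodrug dosing), `02_phantom_ion_images.py` (why raw intensity
misleads), `04_segmentation.py` (organ recognition, ARI 1.000),
`05_timecourse_pk.py` (AUC/TE/RTE).

The pipeline is also scriptable from the shell:

```bash
vcqmsi run --out results_dir        # full synthetic analysis + metrics.json
vcqmsi simulate --out phantom_dir   # phantom as imzML + ground-truth CSVs
vcqmsi benchmark --spreads 1,5,10   # calibration benefit vs matrix spread
```

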