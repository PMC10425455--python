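# Methods

This note documents the models implemented in `hsifruit`, the design of the
synthetic-data generator the tests run on, and the numerical choices made
where the underlying procedures are conventionally under-specified.

## Reference chemistry

Colour is summarised by the statistic *e* = 1000 *a*\*/(*L*\* · *b*\*)
computed from CIELAB coordinates; it contrasts the red–green axis against
lightness × yellow–blue and rises monotonically as loquat ripens from green
to orange. Maturity stages are defined on *a*\* with thresholds 8.33 and
15.41; both boundary values are assigned to stage II (closed interval) so
the three stage predicates partition the real line — the verbal definition
("less than", "between", "greater than") leaves the boundaries ambiguous.
All standard deviations in the package use the n−1 denominator, including
the SD entering RPD.

## Cube correction and segmentation

Reflectance correction is the standard black/white normalisation
*I* = (*I*₀ − *B*)/(*W* − *B*), applied voxel-wise; it is exactly invariant
to any common positive gain on the three inputs. Raw counts below the dark
floor (sensor noise) give small negative reflectances, which are clipped to
zero and counted in the log. Fruit/background segmentation is not part of
the scientific contribution and is implemented as a deterministic
engineering step: Otsu's threshold on the mean reflectance over a
high-contrast NIR window (750–850 nm, where fruit tissue is bright and the
stage background dark), followed by hole filling and removal of components
smaller than `min_area` pixels.

## SNV and splitting

SNV centres and scales each spectrum independently (mean 0, SD 1, n−1),
which removes per-sample multiplicative gain and additive offset exactly —
the scatter model that surface curvature and light-path changes induce.
SNV is idempotent.

Both splitters are deterministic farthest-point algorithms. Kennard–Stone
seeds with the sample pair at maximal Euclidean distance (lowest indices on
ties) and greedily adds the point with the largest minimum distance to the
selected set. SPXY applies the same selection to the sum of the X- and
y-distance matrices, each normalised by its maximum (y standardised first),
so the calibration set covers both spectral and response space. Split sizes
round half away from zero; the stratified 2:1 variant computes per-class
sizes the same way and repairs ±1 on the classes with the largest rounding
remainders so the totals match the global rounding. This reproduces the
canonical 105/35, 90/30 and 166/83 splits exactly. Tie-breaking everywhere
is "lowest index wins", making both algorithms exactly reproducible.

## Wavelength selection

**CARS** runs `n_runs` = 50 Monte-Carlo iterations. Each iteration fits a
PLS model on a random 80% calibration subset, weights every surviving band
by the absolute value of its regression coefficient, force-retains the top
fraction given by the exponentially decaying schedule *r*ᵢ = *a*·e^(−*k·i*)
with endpoints *r*₁ = 1 and *r*₅₀ = 2/*p* (the standard two-point
calibration of the decay constants), and then applies adaptive reweighted
sampling — *n* weighted draws with replacement among the retained bands,
keeping the uniques — so low-weight bands drop out stochastically. Each
surviving subset is scored by 5-fold cross-validated RMSE, and the subset at
the trace minimum wins. The inner PLS latent-variable count is chosen once,
by 5-fold RMSECV on the full spectrum (cap 10), and reused as
min(count, #bands, subset size − 1) inside the loop; selecting it anew at
every iteration multiplies the cost of the run by the fold count while the
selected subset on the synthetic benchmark is unchanged, so the one-shot
choice is the default. Monte-Carlo selectors first sort samples into a
canonical order (by response, then leading bands) so results are invariant
to permuting the input rows under a fixed seed.

**GA** uses binary chromosomes over bands, fitness = −RMSECV of a PLS model
on the encoded subset, tournament selection of size 2, single-point
crossover (probability 0.5), bitwise mutation (0.01), elitism of one, and
100 generations with a population of 30 — the conventional settings for
band selection. The all-zero chromosome is assigned −∞ fitness and never
fitted. Initial chromosomes switch bits on with probability 0.3, biasing
the search toward sparse subsets. Fitness values are cached by chromosome,
and elitism makes the best-ever fitness non-decreasing.

**SPA** grows, from every candidate start band, a chain that repeatedly
adds the band whose column has maximal norm orthogonal to the span of the
chain so far (classical successive projections, implemented by explicit
deflation); chains truncate when the maximal residual norm falls below a
relative tolerance of 1e−10 (collinear exhaustion). Every (start, length)
chain is scored by the validation RMSE of an OLS model on an SPXY 3:1
sub-split of the calibration data, and the global minimiser is returned.
SPA has no randomness.

## Calibration models

* **PLSR** — NIPALS PLS (scikit-learn backend); latent variables by 5-fold
  RMSECV (cap 20) with a one-standard-error preference for fewer
  components. With LVs equal to the rank of X, predictions coincide with
  least squares (asserted in tests).
* **PCR** — PCA scores + OLS, component count likewise (cap 30).
* **MLR** — ordinary least squares on the selected bands; requires
  n > #bands + 1 and a full-rank design, otherwise it raises with advice to
  select fewer bands.
* **ELM** — single hidden layer (default 40 nodes, sigmoid) with fixed
  uniform(−1, 1) weights and pseudo-inverse output weights. Inputs are
  scaled per band to [−1, 1] to keep the sigmoid out of saturation. With
  linear activation and identity hidden weights the network reduces exactly
  to least squares, the algebraic sanity check used in tests.
* **BP** — one hidden layer (default 10 nodes, sigmoid, linear output)
  trained by stochastic gradient descent with early stopping on an inner
  validation split (scikit-learn `MLPRegressor`); inputs scaled to [−1, 1],
  target standardised internally. Both network sizes are conventional
  defaults and are exposed as hyperparameters.

Evaluation follows the standard definitions: R² = 1 − SSE/SST about the
set's own mean, RMSE with a 1/n denominator, RPD = SD(measured prediction
set, n−1)/RMSEP. RPD tiers: < 1.5 poor, [1.5, 2) moderate, [2, 2.5] good
(the 2.5 boundary goes to "good", since "higher than 2.5" defines
excellent), > 2.5 excellent. A perfect prediction set (RMSEP = 0) makes RPD
undefined and raises rather than returning infinity. Reported percentages
are rounded to two decimals only in report objects; internal computation is
full precision.

## Published reference models

The optimal CARS-MLR model equations for the three quality parameters are
shipped as JSON fixtures (intercepts 22.89 / 13.36 / 36.33; 20 / 29 / 18
feature bands), together with all nine published band subsets
(CARS/GA/SPA × three targets). Printed wavelengths are mapped to grid
bands by nearest neighbour with an error if a wavelength is further than
half the band spacing from the grid; on a uniform 256-band grid a couple of
adjacent printed pairs (e.g. 705/707 nm) share a band, which is expected —
the instrument's native grid is not perfectly uniform.

## Maturity classification

PLS-DA regresses a one-hot stage indicator matrix by PLS (LVs by inner
stratified CV on accuracy, fewest LVs on ties) and classifies by argmax of
the predicted scores. "Simplified K nearest neighbour" is implemented as
nearest class centroid — each stage collapses to its mean training
spectrum; this is the most common reading of "simplified", but the term is
not standardised, so the implementation is isolated behind the family enum
and a drop-in alternative is straightforward. The SVM is RBF-kernel,
one-vs-one, with (C, γ) from a 5-fold grid search over powers of two
(2⁻⁵…2¹⁰ × 2⁻¹⁰…2³), deterministic because the folds are unshuffled.
All argmax/argmin ties break toward the earlier stage (I < II < III).
Classification uses full-spectrum SNV spectra; no band selection.

## Pixel-wise maps and deviation compression

Fruit are near-spherical, so per-pixel spectra vary strongly with surface
curvature even at constant composition. For visualisation, each fruit-pixel
spectrum *p* is replaced by *m* + *c*(*p* − *m*) where *m* is the mask-mean
spectrum and *c* ∈ [0, 1] (default 0.5; the conventional value is not
printed anywhere, so it is configuration, recorded in the output metadata).
Compression preserves the mean spectrum for every *c* and shrinks map
variance monotonically in *c*. The linear quality model is then applied per
pixel at its bands; if the model's stored preprocessing tag is SNV, each
pixel spectrum is SNV-treated over the full grid first. The colour scale
defaults to the observed prediction range (configurable to the calibration
range for cross-fruit comparability); the palette is any matplotlib
colormap and is presentation, not behaviour.

## Synthetic-data generator

The generator defines the study conditions for all property-based tests.

**Quality tables.** Stage counts follow the requested proportions (largest
remainder allocation; default 0.27/0.51/0.22, a harvest skewed toward
mid-ripe fruit). Per stage, *a*\* is drawn from a Gaussian truncated to the
stage's defining interval (means 3/12/19, SDs 3/2/2.5), *L*\* falls and
*b*\* rises slightly with ripening (62→54, 38→44), and colour *e* is
computed from the formula, which places it in the 1.2–9 range typical of
loquat. Firmness falls (means 3.2/2.4/1.5 kg/cm², SD ≈ 0.4) and SSC rises
(6.5/7.8/9.3 °Brix, SD 0.8) with stage, reproducing the observed ripening
trends as orderings; the exact numbers are configuration, not claims.

**Spectra.** 256 bands on 390–1030 nm. A smooth sigmoidal continuum (low
visible, high NIR reflectance) minus a chlorophyll Gaussian dip at 675 nm
whose depth decreases linearly with *a*\* (ripe fruit lose chlorophyll) and
a water dip at 980 nm. Each quality target additionally loads on five
dedicated bands: band *j* of target *q* carries amplitude 0.02 ·
(*z_q* + 0.35 ε*_j*), where *z_q* is the fruit's standardised target value
(fixed population location/scale, so spectra are a pure function of the
quality vector) and ε is a pseudo-random but *deterministic* function of
the quality vector (hash-seeded). The ε term makes the five bands
correlated but not collinear, so recovering the target well genuinely
requires (most of) all five — this is what makes "CARS finds ≥ 4 of the 5
true bands" a meaningful recovery criterion rather than a test of
tie-breaking among redundant bands. Per-sample multiplicative gain
(SD 0.08) and additive offset (SD 0.04) emulate the scatter SNV removes;
i.i.d. noise (SD 0.005) is added last and reflectance is clipped to
[0, 1.2], mirroring corrected reflectance occasionally exceeding 1.

What the generator does **not** emulate: instrument line-shape and
band-to-band correlated noise, specular highlights, stem/calyx tissue,
batch effects between imaging sessions, and any nonlinear
spectrum–composition coupling. Passing the recovery tests therefore shows
the algorithms are implemented correctly and can extract linearly encoded
composition from realistic-looking spectra; it does not certify real-fruit
performance figures.

**Scenes.** An ellipsoidal fruit region carries the record's clean spectrum
under radial shading normalised to mean 1 over the mask (so the mask-mean
corrected spectrum equals the generating spectrum up to noise), on a dark
flat background; white/dark reference cubes are built so the black/white
correction inverts exactly. Each fruit is treated as one colour reading —
whether reference colour was measured at one spot or averaged is left open
by convention, and one reading is the simpler model.

## Problem sizes and determinism

Default test and benchmark sizes are 200 samples for regression recovery
(20 CARS seeds), 500 for classification, and 32–40 px scenes — sizes at
which every property in the suite is stable across seeds while the whole
suite runs in well under a minute per module. All stochastic components
(Monte-Carlo sampling, CV fold shuffling, network initialisation) are
driven by explicit integer seeds; SPA, the splitters and SNV are exactly
deterministic. Known numerical edge cases: constant spectra (SNV undefined,
raises), uniform cubes (no Otsu bimodality, raises), perfect predictions
(RPD undefined, raises), collinear band subsets (MLR raises; SPA truncates
chains).
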