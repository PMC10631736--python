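# Methods

`patterncells` implements the complete analysis chain used to decide
whether a direction-tuned visual neuron is a true nonlinear motion
integrator (a *pattern* cell) or a linear moving-edge detector (a
*component* cell), together with a synthetic-data generator that
produces recordings with known ground truth.  This note documents the
models, the conventions adopted where the underlying procedures admit
choices, and what the synthetic data does and does not emulate.

## Stimuli

All stimuli are luminance movies (values in [0, 1], 0.5 = mid-gray) on a
flat display spanning 120° of azimuth × 90° of elevation.  Direction 0°
is rightward drift; angles increase counter-clockwise.

* **Gratings** — `L(x,y,t) = 0.5 + 0.5 c cos(2π(f·u − w·t) + φ₀)` with
  `u` the coordinate along the drift direction, spatial frequency `f`
  (protocol: 0.02 and 0.04 cycles/deg), temporal frequency `w` (2 and
  6 Hz), contrast `c` (protocol: 1), duration 1.5 s.  Spatial phase
  φ₀ = 0 throughout (irrelevant after trial averaging; fixed for
  reproducibility).
* **Plaids** — additive superposition around mid-gray of two gratings at
  the pattern direction ± half the cross-angle (default 120°), each at
  half contrast.  Out-of-range luminance is clipped with a warning.
* **Correlated noise** — Gaussian white noise filtered with an AR(1)
  (exponential) kernel in time and a Gaussian kernel in space, then
  multiplied by a slow sinusoidal contrast envelope, clipped at ±3σ and
  mapped affinely into [0, 1].  `spatial_corr` (default 12°) is the
  half-width at half-maximum of the spatial autocorrelation;
  `temporal_corr` (default 0.08 s) sets the lag-1 frame correlation to
  `exp(−Δt/τ)`.  The exponential temporal kernel was chosen over a
  Gaussian one so the lag-1 correlation has this closed form; the
  temporal scale balances stimulus power across the 2 Hz and 6 Hz
  channels of the protocol.  Contrast modulation: period 10 s, depth 0.3.
  The same seed always yields a bit-identical movie.

Movies are generated at reduced resolution (64 × 48 pixels for the full
protocol, 48 × 36 for desk-scale runs); a guard enforces ≥ 4 samples per
cycle of the highest spatial frequency.  Frame counts round
`duration × frame_rate` to the nearest integer.

## Model neurons

All units share a front end of space–time-oriented Gabor filters: a
spatial Gabor whose carrier phase advances across 10 lags (33.3 ms per
lag, one noise frame) at the unit's preferred temporal frequency, under
a Hann temporal envelope.  The envelope width along the drift axis is
`envelope_sigma` (default 10°); the width along the orthogonal
(orientation) axis is `aspect_ratio × envelope_sigma` — high aspect
ratio means an elongated edge detector, low means a "blobby" RF.

Filter outputs are divisively normalized by the pooled stimulus contrast
(per-frame RMS luminance contrast smoothed over the filter's temporal
window, plus a semi-saturation constant c50 = 0.01).  This contrast gain
control is the standard cortical normalization model; it is essential
here because a static LN unit calibrated to fire ~30 spikes/s for a
full-contrast grating would otherwise be nearly silent for the
low-contrast noise movies, unlike real neurons.  The pool is
unselective, so normalization rescales responses per stimulus without
changing any direction-tuning shape, and it produces genuine
cross-orientation suppression: the preferred plaid drives the unit at
half contrast per component, so peak plaid responses are suppressed
relative to gratings (positive CSI), as observed in cortex.

The four unit kinds:

* `ln_component` — one high-aspect filter (aspect drawn from 2.5–3.5),
  half-squaring output nonlinearity (`max(d,0)²`).  Fires to the plaid's
  component gratings: plaid tuning peaks ±60° from the grating peak.
* `ln_blobby` — same LN architecture with aspect 0.25–0.35 and a more
  expansive output (power 3).  Its broad direction tuning merges the two
  plaid peaks into one at the grating peak: a purely linear pattern
  mimic.  The expansive exponent is what makes this mimicry robust; at
  power 1 the merged curve still correlates best with the component
  prediction.  These units prefer the low-SF/low-TF protocol condition
  by construction — blobbiness is relative to the stimulus scale and
  only exists at wavelengths much longer than the RF envelope.
* `energy_complex` — sum of squared outputs of a quadrature Gabor pair:
  a phase-invariant complex-cell analog (modulation index < 3).
* `pooled_pattern` — the motion integrator: twelve motion-energy
  subunits (quadrature pairs, one per 30° of preferred direction, random
  spatial phases) pooled with signed cosine weights centred on the
  unit's preferred direction (motion opponency), then rectified.  This
  is the classical dorsal-stream construction: for a 120° plaid the
  subunits at ±60° drive the pool exactly when the *pattern* moves along
  the unit's preferred direction, so grating and plaid tuning coincide.
  Because the subunits are phase-invariant, the unit has no dominant
  linear kernel; a small "linear leak" (0.2 × the in-phase subunit's
  rectified-squared output) leaves the weak residual STA structure seen
  in real pattern cells.  Phase-locked (simple-cell) subunits were
  deliberately not used: pooling rectified simple subunits is linear in
  the subunit rates, so the pooled plaid tuning equals the component
  prediction of the pooled grating tuning and the unit reads out as a
  component cell — and the coherent sum of aligned subunit filters is
  itself a strong linear kernel, giving the pattern unit the *sharpest*
  STA instead of the weakest.

Gain is calibrated per unit so the noiseless response to the preferred
full-contrast grating peaks at 30 spikes/s above a spontaneous baseline
of 1 spike/s (anesthetized-cortex range; the baseline is kept low so
spontaneous spikes do not drown the noise-movie STA).  Spiking is
inhomogeneous Poisson per trial.  Population preferred directions tile
the 12 protocol directions; carrier SFs sit at 0.02 cpd (rodent RF
spatial scales cluster there — the 0.04 cpd battery condition probes the
units off-peak) and TF preferences skew low (3:1 at 2 Hz vs 6 Hz).

A session interleaves, in seeded random order with 1-s gray
interstimulus intervals: 20 trials of every grating and plaid condition
(2 SF × 2 TF × 12 directions, 1.5 s each) and twenty 60-s noise movies.

## Tuning metrics

Responses `R_x` are trial-averaged firing rates over the full stimulus
window, z-scored against the distribution of rates in the 1-s
interstimulus windows (SD floored at 0.1 spikes/s), negatives clipped to
zero.  A unit is *responsive* if some grating or plaid condition exceeds
both 2 spikes/s (baseline-subtracted) and 6 z-scored points.

* **DSI** = (R_pref − R_opposite)/(R_pref + R_opposite); direction
  selective if DSI > 0.33.  Opposite = preferred + 180° (exact bin
  arithmetic).
* **MI** = |PS(f₁) − ⟨PS⟩| / sd(PS), computed from the periodogram of the
  mean-subtracted 10-ms-bin PSTH of the most effective grating, DC bin
  excluded, f₁ mapped to the nearest frequency bin.  MI > 3 marks
  simple-like (phase-sensitive) units, MI < 3 complex-like.
* **CSI** = (Rg − Rp)/(Rg + Rp) from peak grating and plaid responses:
  +1 = responds to gratings only, −1 = plaids only, 0 = equal.
* **Best condition** — the SF/TF pair maximizing the peak grating
  response; ties resolve to the lowest SF, then the lowest TF.

## Pattern/component classification

For the 12-point curves at the best condition: the ideal component
prediction of the plaid curve is the grating curve summed with itself
shifted ±60° (bin-exact); the ideal pattern prediction is the grating
curve itself.  `rc` and `rp` are the partial correlations of the
observed plaid curve with each prediction, partialling out the other
(the standard dorsal-stream formulation); they are Fisher-transformed
with n − 3 = 9 degrees of freedom: `Z = atanh(r)·3`.  A unit is
*pattern* if Zp > 1.28 and Zp − max(Zc, 0) > 1.28 (one-sided 90%
criterion), *component* symmetrically, else *unclassified*;
PI = Zp − Zc.  Correlations are clipped to ±(1 − 10⁻⁶) before atanh.
A strict mode keeps a label only when the unit classifies identically
at both SFs (used before comparing observed and LN-predicted labels).

Population-average curves circularly align each unit's pair to its
grating peak, normalize by the pair's joint peak, average, and
re-classify the averages.

## STA receptive fields

The raw STA at lag k is the spike-count-weighted mean of the contrast
frames k noise-frames earlier (lags never cross movie boundaries; spike
counts below 100 are flagged low-confidence).  Decorrelation divides the
per-lag 2-D spectrum by the stimulus spatial power spectrum, ridge
regularized at 0.1 × its maximum (an optional lag-axis whitening against
the stimulus temporal autocorrelation exists but is off by default — at
realistic spike counts it amplifies noise more than it removes bias).
Pixelwise z-scores come from a permutation null: the observed number of
spikes redistributed uniformly over the noise frames, 200 permutations,
the null STAs decorrelated identically.

* **CI** (contrast index) — mean of the top 1% of |z| in a frame.
* **Gabor fit** — bounded least squares with 8 orientation-seeded
  starts; R² = 1 − SSres/SStot.
* **Lobes** — connected regions (8-connectivity, ≥ 4 pixels, positive
  and negative separately) of the best-CI frame binarized at |z| > 3.5.
* **Dominant SF** — radial position of the global peak of the
  mean-subtracted, Hann-windowed, zero-padded amplitude spectrum of the
  best frame (a ring average would bias low for oriented spectra).
* **Exclusion floor** — a unit enters the LN-prediction analysis only if
  its best-frame CI exceeds the 95th percentile of the *per-permutation
  maximum* null CI over the 10 lags (the observed statistic is a max, so
  the null must be max-corrected).

## LN prediction

The significance-weighted STA reconstruction — the pixelwise z-scored
frames, with pixels whose |z| ≤ 3 removed (keeping only connected
significant regions of ≥ 4 pixels), smoothed by a 1.5-pixel Gaussian and
bicubic-upsampled ×2 — is used as the filter of an LN model: space–time
convolution with the 12-grating + 12-plaid battery at 0.02 cpd and the
unit's best TF, half-wave rectification to power 3, time-averaging,
peak normalization.  The significance masking matters: without it,
estimation noise in the filter reshapes the low-contrast tuning of
broadly tuned units and their predicted labels flip erratically.  The readout power matches the most
expansive output nonlinearity in the unit family.  Zc′/Zp′ and the
predicted label are computed from the predicted curves exactly as for
observed ones; flat predictions (empty masked filter) are flagged
unpredictable.  Transitions (to same / to opposite / to unclassified)
are summarized per observed class over units that classify consistently
at both SFs and pass the CI floor.

The expected outcome — the package's core scientific contract — is that
linear units (component *and* blobby mimics) retain their observed
classification under this round trip, while pooled pattern units lose
theirs, with Zp′ collapsing toward zero: linear-RF geometry cannot
explain true motion integration.

## Regressor-bank models

Each unit's concatenated 24-point tuning (12 grating + 12 plaid bins,
peak-normalized) is fit by ridge regression on the tuning curves of a
bank of reference units (≥ 12 members, preferred directions tiling the
circle): a component bank (high-aspect LN units), a pattern bank
(opponent energy pooling, no leak), and an "unclassified" bank (pooled
units with random signed weights, resampled until they fail both
classification criteria).  Cross-validation holds out 3 of the 24
direction bins per fold (8 deterministic folds, each mixing grating and
plaid bins); the ridge penalty is chosen per outer fold by an inner CV
over 7 log-spaced values.  The best bank is the cv-RMSE argmin;
confidence = (second-best − best)/second-best ∈ [0, 1), with > 0.3
counted as high confidence.  Matched banks should win for component and
pattern cells; heterogeneous targets are fit poorly by everything.

## Problem sizes

The full protocol (50 units, 20 trials, 20 × 60 s noise, 64 × 48 pixels,
200 permutations) is the generator default.  The analysis scripts and
the validation suite run a desk-scale configuration — 24 units
(8 component, 6 blobby, 6 pattern, 4 complex), 48 × 36 pixels, the full
noise protocol — which preserves every qualitative result while keeping
a complete run in a few minutes on one core.  STA parameter-recovery
checks use a single LN unit with a power-1 (classical) output stage,
the regime in which the STA is the canonical estimator.

## What the generator does and does not emulate

It emulates: the full stimulus protocol and trial structure, Poisson
variability around rate codes, contrast gain control, and the
qualitative population structure (sharp vs blobby linear RFs, energy
complex cells, opponent-pooling integrators).  It does not emulate:
non-Poisson spiking statistics, adaptation, eye movements, RF-position
scatter (all RFs are display-centred), laminar or areal structure,
correlated population noise, or spike-sorting artifacts.  Passing tests
on this data therefore validate the analysis chain and its internal
logic, not the biological claims themselves: percentages of pattern and
component cells in real cortex are properties of the recordings, not of
this artifact.

## Known limitations

* The blobby/pattern decision boundary is intrinsically delicate: blobby
  units sit near it by construction, so their labels under noisy
  prediction are the least stable quantity in the pipeline.
* The STA of expansive (power ≥ 2) units under correlated noise carries
  a shape bias that ridge whitening removes only partially; filter
  recovery saturates around r ≈ 0.9 even with generous data.
* The noise movies are spatially low-pass, so units preferring 0.04 cpd
  or 6 Hz are weakly driven and their STAs often fall below the CI
  floor — matching the empirical observation that recoverable RF scales
  cluster near 0.02 cpd.
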