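# Methods

This note documents the models implemented in `thzchem`, the conventions
they fix, the defaults and why, and what the synthetic data do and do not
establish about real measurements.

## Forward model (`thzchem.simulate`)

**Pulse.** The reference field is a Gaussian-derivative single cycle,
`E(t) ∝ -(t-t0)/τ · exp(-(t-t0)²/2τ²)`, the usual idealisation of
photoconductive-antenna emission. With the default width τ = 0.3 ps its
power spectrum peaks near 1/(2πτ) ≈ 0.53 THz and carries usable energy
across 0.2–2 THz. Defaults: 2048 points at 0.02 ps (41 ps window,
24.4 GHz resolution, 25 THz Nyquist), pulse centred at 8 ps so that
sample-induced delays of a few ps stay well inside the window.

**Slab transmission.** A sample of thickness *d* (default 1 mm, pressed
pellet) multiplies the reference spectrum by

    H(ω) = [4n/(n+1)²] · exp(-α d/2) · exp(-i ω (n-1) d / c),

i.e. two air/slab interface losses, Beer–Lambert field attenuation, and
the excess propagation delay. This is the single-pass model: etalon
(Fabry–Pérot) echoes from the pellet faces are deliberately omitted; a
`fresnel="complex"` option evaluates the interface factor with the full
complex index N = n − ik instead of the real part. The default uses the
real part so that the forward model is the *exact* inverse of the
standard extraction formulas below — the loss correction to the interface
term is second order in k (k ≈ 0.1 here) and evaluating it would bias the
round trip by ~6×10⁻⁴ in n at 1 THz, which matters when the simulator is
used as an oracle for the extractor.

**Conventions (fixed once, used everywhere).**

* Fourier kernel `exp(-i 2π f t)` (numpy `rfft`); a pure delay Δt
  multiplies bins by `exp(-i 2π f Δt)`.
* φ is the *positive phase lag* of the sample, `-arg(E_sam/E_ref)` after
  unwrapping, so n > 1 ⇒ φ > 0.
* k = αc/(2ω): α is the *intensity* absorption coefficient (cm⁻¹), k the
  field extinction coefficient. The DC bin, where the conversion
  diverges, carries k = 0.

**Material model.** Per sample of class c:

    α(f) = α₀(c) + s·f + A(c)·bump(f; band) + δ₀ + δ(f)      [cm⁻¹]
    n(f) = n₀(c) + δ_n(f)

* `α₀, s`: featureless affine rise (default slope 10 cm⁻¹/THz), as
  expected for disordered amorphous organics. The default eight class
  offsets are calibrated so the band-average (0.2–1.5 THz) absorption of
  each class equals the published per-variety means (35.3–42.3 cm⁻¹).
* `A(c)·bump`: raised-cosine absorption band confined to 0.773–0.845 THz
  with amplitude 1 + 1.5·(c−1) cm⁻¹. The amplitude is linear in the class
  code because the regression response *is* the class code (PLS1); the
  band coincides with the 8th width-8 interval of the default
  128-variable grid, mirroring a design in which the informative band is
  one interval wide.
* `δ₀ ~ N(0, 2.0 cm⁻¹)`: per-sample constant offset — pellet-to-pellet
  thickness/packing-density scatter (~5% of the absorption level), the
  dominant nuisance in pressed-pellet transmission work. It makes the
  *global* absorption level an unreliable class cue, while band-local
  contrasts stay clean.
* `δ(f)`: smooth zero-mean curve (six cosine modes, pointwise SD
  0.5 cm⁻¹, envelope rising ×3 from the low to the high end of the band)
  — slowly varying compositional/scattering structure.
* `n₀(c) = 1.5 + 0.003(c−1)` plus a smooth deviation of SD 0.005: the
  refractive index is nearly class-blind by design, so absorption is the
  better feature, and no Kramers–Kronig consistency between the n and α
  deviations is enforced.

**Noise and acquisition protocol.** Each sample is scanned three times;
one reference scan is taken per block of three samples and shared by that
block. Each scan receives (a) multiplicative Gaussian noise per frequency
bin (SD 0.5%) — gain/alignment fluctuation — and (b) additive white
time-domain noise (SD 0.001 field units), whose flat spectral floor sets
the dynamic range (~46 dB below the spectral peak). Because the sample
spectra are attenuated by e^(−αd/2) ≈ 0.1, their SNR crosses ~1 near
1.6–1.7 THz, i.e. the band above 1.5 THz is noise-degraded, which is why
the feature matrices stop at 1.5 THz.

**Calibration of the signal level.** The free knobs (bump amplitude step,
deviation SDs, noise SDs) are not estimates of wheat chemistry — no raw
data exist to estimate them from. They were calibrated once, during
design, so that the synthetic session reproduces the within-class
predicted-value dispersion (~±0.2–0.3 class units) that published THz
discriminations of this kind exhibit, and were not revisited afterwards.

## Extraction (`thzchem.extraction`)

Scans of a sample are averaged pointwise; the average and its block's
reference are Fourier-transformed (optionally zero-padded) and ratioed
over the requested band (widened by two FFT bins so resampling onto the
band endpoints is always covered). Reference bins below 10⁻⁴ of the
in-band maximum abort the deconvolution with a list of dead bins rather
than being regularised. The phase is unwrapped along increasing frequency
and anchored by subtracting the integer multiple of 2π that minimises the
intercept of a straight-line fit of φ(f) over 0.2–0.5 THz — the physical
φ(f) of a non-dispersive slab passes through the origin. The inversion

    n = 1 + φc/(ωd),   α = (2/d)·ln[4n/(ρ(n+1)²)]

is applied per bin; α is reported in cm⁻¹ and *not* clipped when noise
drives bins slightly negative (a warning flags them). Feature matrices
are built by linear interpolation of α(f) or n(f) onto a linear grid of
128 points spanning 0.2–1.5 THz inclusive (the grid is a configuration
choice echoed into every output file). Noiseless round trips recover
planted n to ~10⁻¹⁴ and α to ~10⁻¹⁴ cm⁻¹; the test suite enforces 10⁻⁴ /
10⁻² over 0.3–1.4 THz.

## PLS (`thzchem.pls`)

NIPALS PLS1 on column-centred X and centred y; no variance scaling (all
variables share units). The regression vector is B = W(PᵀW)⁻¹q. Scores
are orthogonal by construction (tested to 10⁻⁸ relative); at full rank
the predictions coincide with pseudoinverse least squares (tested to
10⁻⁶, and independently against scikit-learn's `PLSRegression` with
`scale=False`). If the covariance is exhausted before the requested
number of components — routine on interval slices, because the
128-variable grid is finer than the native FFT grid and narrow intervals
are exactly rank-deficient — extraction stops with a warning and the
model keeps the components actually extracted.

Metrics: RMSE(y_ref, y_pred) = √(Σ(y_ri−y_pi)²/n), serving as RMSEC /
RMSECV / RMSEP depending on which predictions are supplied, and the
Pearson correlation R. Class assignment rounds a prediction to the
nearest integer in 1..K; exact half-way points round *up* (1.5 → 2), and
out-of-range values clamp to the extreme classes. The calibration /
prediction split is stratified by class (default fraction 0.6: 96/64 for
8×20) and reproducible from its seed; both sets must retain at least two
members of every class.

The leave-one-out loop refits the full NIPALS model without each sample
in turn; with n ≤ 160 and p ≤ 128 a full LOO costs well under a second,
so no shortcut (kernelised CV, PRESS updates) is used.

## Interval PLS (`thzchem.ipls`)

The variable axis is partitioned into consecutive blocks of
`interval_width` variables (1-based inclusive indices); a remainder
shorter than one width is merged into the last block. Per interval the
factor count is capped at the interval's variable count, a full LOO CV is
run, and the interval with minimum RMSECV is selected, ties broken by the
lower index. The report carries the full-spectrum RMSECV for comparison
and the complete per-interval table (indices, frequency span, factors,
RMSECV, R) for re-plotting.

**When does iPLS beat the full spectrum?** When the out-of-band variables
carry noise that is *unrelated* to the in-band nuisance, the full model
pays for 120 irrelevant variables and the selected interval wins (the
planted-band study below shows this at ≥90/100 seeds). In the default
end-to-end conditions, however, the per-sample deviations are globally
smooth: the full-spectrum model can *use* out-of-band variables to
estimate and subtract each sample's nuisance curve, and full-spectrum and
best-interval RMSECV come out statistically comparable. Both behaviours
are real properties of interval selection, and the package reports the
comparison rather than assuming an ordering.

## Pipeline (`thzchem.pipeline`)

One configured run simulates the session, extracts both feature types,
applies one shared stratified split, fits and LOO-cross-validates the
full-spectrum models, runs iPLS at each configured width on the
absorption calibration set, and evaluates every selected model on the
held-out prediction set. All stages are deterministic given the two seeds
(simulation, split). Persisted artifacts — trace files (two-column text),
matrix CSVs with a JSON sidecar and content hash, model JSONs carrying
the training-matrix hash, interval tables, and the run report — are
sufficient to recompute every reported number
(`pipeline.modelling_from_matrices` does exactly that, and a test asserts
bit-level agreement).

## Problem sizes used by the test and acceptance runs

Chosen to exercise the full design at desk scale: the default session is
8 classes × 20 samples × 3 scans (matching the published experiment's
design); the planted-band interval study runs 100 seeded repetitions of
8 classes × 12 samples on matrices drawn directly in the frequency domain
(the time-domain route is validated separately by the round-trip and
end-to-end tests); oracle-equivalence checks use 100 random 12×6
problems. The whole suite runs in well under a minute on one core.

## Known limitations

* Etalon echoes, water-vapour lines, detector nonlinearity and delay-line
  jitter are not modelled; thickness is treated as exactly known (no
  echo-based thickness estimation, no Fabry–Pérot correction).
* The ordinal class coding (PLS1 on y = 1..8) is inherited knowingly:
  class separability then depends on the arbitrary class ordering.
  One-hot PLS-DA is out of scope.
* Samples are simulated in class order, and reference scans are shared by
  blocks of three consecutive samples, so reference drift is mildly
  class-correlated — as in a real un-randomised acquisition session. At
  very small n this lets even the nearly class-blind refractive-index
  feature score above chance.
* The generator's deviation magnitudes are design choices, not estimates;
  passing tests demonstrate that the *pipeline* is correct and that the
  chemometric conclusions hold under the stated statistical structure,
  not that real wheat spectra have that structure.
* The paper-style headline metrics computed on real spectra are not
  reproducible from synthetic data and are not targets; only qualitative
  orderings (absorption feature beats refractive index; interval
  selection finds the planted band) are asserted.
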