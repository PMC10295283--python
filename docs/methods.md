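# Methods

`nirscast` implements a reference-free scheme for removing physiological
noise from functional near-infrared spectroscopy (fNIRS) hemoglobin signals.
Conventional activation analysis needs a modeled hemodynamic response
function (HRF) as a regressor; when the task timing is unknown, or a noise
rhythm (e.g. the ~0.1 Hz Mayer wave) sits on top of the response band, that
model is unavailable or misleading. The scheme implemented here instead
*learns the noise from the resting state and extrapolates it through the
task window*:

1. decompose the resting-state signal with an 8-level maximal overlap
   discrete wavelet transform (MODWT, sym4);
2. train one recurrent (LSTM) forecaster per low-frequency component
   ("wavelets 5–9" = details D_5…D_8 plus approximation A_8);
3. forecast each component 244 samples (30 s at 8.138 Hz) past the end of
   rest, which preserves the *phase* of each noise rhythm at task onset;
4. subtract the summed predictions from the measured task segment.

A task-evoked response present in the measurement is, by construction, not
in the forecast; it therefore survives subtraction, and shows up as excess
prediction error when forecasts are scored against the measured
continuation. That error gap between records with and without a response is
the method's detection signal.

## MODWT

The transform follows the circular ("mod n") definition: level-j
coefficients are the circular convolution of the signal with the periodized
equivalent filter h̃_j (the base DWT pair rescaled by 2^{−j/2} and cascaded
with upsampled scaling filters); the multiresolution analysis (MRA) inverts
each level by circular cross-correlation with the same filter. Both
directions are evaluated exactly in the Fourier domain — this is a literal
evaluation of the defining sums, verified in the tests against a brute-force
O(n²) implementation. The transform is defined for arbitrary n, is
shift-equivariant, conserves energy, and the MRA components add back to the
input to round-off.

Numerical tolerances used in the invariants: reconstruction 1e−8 relative,
energy 1e−6 relative, shift equivariance and oracle agreement 1e−10.

The decomposition level is fixed at J = 8 everywhere (chosen by the rule
"largest integer strictly below log2(n)" applied to the *shortest* segment
used, 60 s ≈ 488 samples), so every segmentation condition works with the
same nine components. The nominal dyadic band of D_j at 8.138 Hz is
[fs/2^{j+1}, fs/2^j]; for D_8 that is [0.0159, 0.0318] Hz, and A_8 holds
everything below 0.0159 Hz. (Published descriptions of these bands sometimes
round to [0.017, 0.035] Hz; we report the dyadic values.)

Boundary handling is purely circular — no reflection or zero padding. A
consequence worth knowing: the decomposition of a *segment* and the
decomposition of the *full record* disagree near the segment ends, because
the wrap-around joins different data. The pipeline deliberately trains on
the segment decomposition (all a causal analysis could see) and scores
against the full-record decomposition (the best available estimate of the
component during the task window), so this boundary mismatch is part of the
measured prediction error, exactly as it would be in practice.

## Synthetic data generator

Each record emulates a 640-s single-channel HbO trace at 8.138 Hz: 600 s of
rest followed by a 40-s task window. Components, all summed and then offset
so the first sample is exactly zero:

| component | model | defaults |
|---|---|---|
| baseline | stable AR(30), unit variance, scaled | amplitude U[0.01, 0.03] a.u. |
| cardiac | constant-frequency sinusoid | f ~ U(0.9, 1.1) Hz, amp U[0.01, 0.03] |
| respiratory | sinusoid | f ~ U(0.24, 0.26) Hz, amp U[0.01, 0.03] |
| Mayer wave | sinusoid | f ~ U(0.09, 0.11) Hz, amp U[0.01, 0.03] |
| very low freq. | sinusoid | f ~ U(0.009, 0.011) Hz, amp U[0.01, 0.03] |
| response (half the records) | two-gamma kernel ⊛ 20-s boxcar, unit peak | amplitude U[0.1, 0.35] |

The AR(30) coefficients are drawn per record as partial autocorrelations
uniform in (−0.5, 0.5), mapped through the Levinson–Durbin recursion — this
guarantees a stationary process for every draw. The two-gamma kernel uses
the canonical parameters (peak delay 6 s, undershoot delay 16 s, unit
dispersions, undershoot ratio 1/6); the response onset is placed immediately
after the rest period, and with a 20-s task plus 20-s recovery its
fundamental frequency (0.025 Hz) falls inside the D_8 band — which is why
wavelet 8 carries the largest detection signal.

What the generator does *not* emulate: motion-artifact spikes, optode
coupling drift, HbR channels, spatial correlation between channels, and the
empirical (non-AR) spectrum of real baseline drift. Passing tests therefore
demonstrate the mechanics and the statistical behaviour of the method under
a controlled noise model, not its field performance.

## Forecaster

Three stacked LSTM layers with [128, 64, 32] hidden units, dropout 0.2
between layers (training only), a linear head on the last hidden state, MSE
loss, Adam (lr 1e−3), minibatch 128, up to 100 epochs. The network,
backpropagation through time, and Adam are implemented in NumPy; gradients
are validated against numerical differentiation in the test suite, and
training is deterministic under a fixed seed.

Supervised pairs are next-sample windows. Each input window spans
`lookback × dilation` samples and reads every `dilation`-th one; windows
slide at full rate. **Dilation** is the one genuinely load-bearing design
choice here: wavelet component j is band-limited below fs/2^j, so it can be
read at a fraction of the full rate without information loss. Forecasting at
the component's natural rate gives the network several cycles of context
(instead of a fraction of one) and shrinks the 244-step recursion to a
handful of steps, which is both faster and far more stable than full-rate
recursion — full-rate one-step recursion on near-band-limited signals tends
to drift over hundreds of steps. The pipeline picks
`dilation = min(2^{j−2}, fit-in-segment cap)` per level (a 2× margin above
the band's Nyquist requirement); forecasts from up to four interleaved
decimated grids are cubic-spline interpolated back to full rate and
averaged. Recursion itself is plain one-step-ahead: each prediction is
appended to the context.

Normalization is a per-series z-score. Training series are standardized by
their own training-segment statistics (a causal choice); a constant series
gets scale 1. One network is trained per wavelet level on all training
records pooled, each record standardized individually.

## Validation protocol

Six segmentation conditions set how much trailing rest feeds the MODWT and
the network: (600, 300), (600, 600), (300, 300), (150, 150), (90, 90),
(60, 60) seconds of (MODWT, LSTM training) data — in samples the training
lengths are [4883, 2441, 1221, 732, 488]. For each condition and each
wavelet 5–9: train on the training records, forecast 244 samples for each
test record, and score MAE = mean |y−ŷ| and RMSE = √(mean (y−ŷ)²) against
the full-record component over the horizon. The with-response and
without-response groups are compared with a Welch two-sample t-test
(unequal variances; the groups have visibly different spreads), flagged at
p < 0.05 (*) and p < 0.01 (**), with no multiple-testing correction.
Windowed errors are *cumulative from task onset*: the w-second window scores
the first round(w·fs) samples, so a slowly rising response produces a gap
that grows with the window.

Errors are reported in normalized units: the reference is standardized with
the *same* training-window parameters as the forecast context, so an error
of 1 means "one resting-state standard deviation of that record's
component". This makes errors comparable across records whose raw component
scales differ by an order of magnitude, and keeps the scoring unit identical
for the with- and without-response groups — scoring each group against a
scale that itself contains the response would absorb part of the detection
signal. A consequence: with-response error magnitudes are a direct readout
of the response-leakage-to-band-noise ratio, so they depend strongly on the
generator's baseline-noise spectrum (see limitations).

For multi-channel recordings a subject-level leave-one-out protocol is
provided: per fold, per-wavelet models are trained on all channels of the
remaining subjects pooled (first 570 s of each channel), and the held-out
subject's channels are forecast 30 s ahead and scored per cumulative window
(1, 3, 5, 10, 15, 30 s).

Desk-scale problem sizes: the shipped experiment runner, the test suite and
the reproduction script use 120 records (100 train / 20 test), 12-20
training epochs and a cap of a few thousand pooled training windows per
level; the full-scale protocol (1000 records, 100 epochs, every window) is a
command-line flag away but takes CPU-days rather than minutes.

## Degenerate inputs and tie-breaks

* Constant series: normalization scale falls back to 1; forecasters
  reproduce the constant.
* Identical zero-variance groups in the t-test: p = 1 by convention,
  flagged as degenerate.
* Groups with fewer than two members: no test, p = NaN in summaries.
* Decomposition levels beyond the select-level rule warn but proceed (the
  protocol itself fixes J = 8 for 60-s segments, where the rule gives 8).
* Sample counts are round(seconds × fs) throughout; the 40-s response
  support may overshoot the record end by the rounding fraction of one
  sample and is trimmed.

## Known limitations

* The AR(30) baseline prior is a stand-in for fitted coefficients from real
  resting fNIRS; real baseline drift carries more very-low-frequency power,
  which shifts the relative scale of in-band noise versus response leakage
  (see the normalization note above).
* Circular boundary handling injects a wrap transient into the last
  ~(2^j−1)(L−1) samples of every segment decomposition; with weak in-band
  noise this transient can dominate without-response prediction error.
* Recursive forecasting carries no uncertainty; confidence bands would
  require an ensemble or a probabilistic head.
* The moving-window task-onset detector (flagging the time at which
  prediction error jumps) is a natural extension and is not implemented.
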