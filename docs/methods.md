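# Methods

## Signal model and scope

The package treats a multichannel surface-EMG recording as a plain numeric
matrix (rows = time samples, columns = muscle channels) with no sampling
rate attached: the file dialect it reads never carries one, so all window
lengths, lags and feature definitions are expressed in samples.  Signals
are assumed finite and regularly sampled; nothing else is required.

## Synthetic EMG generator

`synthetic_emg.simulate_emg` emulates the two qualitative regimes of
physical-action EMG:

- each channel is a stationary AR(2) process (coefficients 0.9, −0.5,
  giving a broad mid-band spectral peak) driven by Gaussian noise and
  rescaled so its baseline SD equals `baseline_sd` (default 1, arbitrary
  units).  The rescaling uses the closed-form stationary variance obtained
  from the truncated MA(∞) impulse response;
- muscle activity is an amplitude envelope: burst starts follow a Bernoulli
  process at `burst_rate` per 1,000 samples, durations are exponential
  (mean 100 samples), and the envelope is `burst_amplitude` inside a burst
  and 1 outside, overlaps taking the maximum.  Bursts are shared across
  channels, as a physical action recruits several muscles at once;
- regime defaults: normal = rate 1, gain 3; aggressive = rate 4, gain 10.
  These are the package's standing study conditions: they make the
  aggressive regime's peak amplitudes several times higher than the normal
  regime's, robustly over seeds, which is the documented qualitative
  contrast between the two activity classes.  Default recording shape is
  10,000 samples × 8 channels, matching the physical-action corpus layout.

What the generator does **not** reproduce: non-Gaussian EMG amplitude
statistics, electrode artefacts, mains interference, inter-channel
correlation structure beyond the shared envelope, and the strong
sample-to-sample predictability of real EMG (see "Why R² ≈ 0.5" below).
Tests passing on this generator therefore validate the algorithms'
contracts, not clinical performance on real recordings.

## Preprocessing conventions

- Standard deviation uses the population (1/N) convention everywhere,
  matching the 1/N normalizations of the window features.
- Robust scaling uses median and IQR = Q3 − Q1 with linear-interpolation
  quantiles.
- A constant channel has scale 0 under standard/robust/min-max scaling; its
  output is defined as 0 rather than raising a division error.
- The row normalizer divides each sample vector by its Euclidean norm and
  leaves all-zero rows at zero.
- Wavelet framing defaults to db4, level 4, symmetric extension, on
  non-overlapping 256-sample frames.  Energy across bands equals signal
  energy exactly only under `mode="periodization"` (the orthogonality
  identity); the symmetric default is kept because it avoids the wrap-around
  artefacts of periodization on burst signals.

## Window features

The ten features follow the classical time-domain definitions listed in the
`features` module docstring.  Conventions worth noting:

- **AAC** divides by N (not N − 1), so WL = N·AAC holds as an exact
  algebraic identity; both forms circulate in the literature and the N
  divisor is the one adopted here.
- **MAV1** uses 1-based indices with unrounded band bounds
  0.25·N ≤ i ≤ 0.75·N, inclusive.
- **SSC** counts interior samples with (X_i − X_{i−1})(X_i − X_{i+1}) ≥
  threshold (the Hudgins form); windows shorter than 3 have no interior
  point and count 0.
- Default thresholds: 0 for ZC and SSC; WAMP defaults to an adaptive
  0.05 × window RMS, a standard choice when sensor units are unknown.  All
  are explicit config fields.
- Trailing samples that do not fill a window are dropped.

## The GMDH network

Training follows the inductive select-and-drop scheme:

1. rows are split sequentially into fitting subset A (first
   `split_ratio` = 0.5 of rows) and validation subset B — sequential rather
   than shuffled so that forecasting validates on later data; a seeded
   shuffled split is available for non-temporal regression;
2. each layer enumerates all unordered input pairs and fits each candidate
   neuron on A by ridge least squares.  Ridge is solved in the augmented
   form `lstsq([B; √λ·I], [y; 0])`: adjacent lag windows of smooth signals
   are nearly collinear, and normal equations (which square the condition
   number) produce garbage coefficients exactly there.  With λ = 0 a
   rank-deficient design falls back to the minimum-norm solution and the
   neuron is flagged degenerate (degenerate neurons are still usable — a
   constant signal makes *every* candidate degenerate yet perfectly
   predictable; training only aborts if no candidate has a finite score);
3. the external criterion is `validate` (MSE on B under the A-fit), `bias`
   (mean over all rows of the squared disagreement between the A-fit and
   B-fit predictions), or their sum `validate_bias` (default).  Candidates
   are sorted ascending, ties broken by pair order for determinism, and the
   best `best_neurons_count` = 30 survive;
4. a layer is accepted when its best score improves the best-so-far by more
   than `epsilon` = 0.001 (an absolute threshold; the first layer always
   counts as an acceptance).  Growth stops when no layer among the last
   `criterion_lookback` = 5 was accepted, or at `max_layers` = 15 (a cap
   the algorithm needs but no external setting fixes; 15 is generous for
   the depths reached in practice, 2–7);
5. the globally best neuron becomes the output and the model is pruned to
   its dependency path; `prune=False` retains the full network, which
   predicts identically (asserted in tests).

Defaults (`linear_cov`, `validate_bias`, λ = 0.5, ε = 0.001, lookback 5,
K = 30, lag 10) follow the settings customarily used for this kind of EMG
forecasting work.  The layer count reported in histories is the number of
layers *attempted*; each entry also records whether it was accepted, since
both conventions exist.

### Reference functions and extrapolation

`linear_cov` and `quadratic` neurons contain product terms.  Composed over
several layers, products turn a modest excursion outside the training
amplitude range into a double-exponential blow-up (an observed failure
mode: one near-unit-root series in ten produced ~1e54 RMSE).  Forecasting
front-ends therefore default to the `linear` reference function — affine
neurons compose to affine maps and cannot blow up — while `linear_cov`
remains the general-purpose default for regression on bounded designs.
This matches the linear-activation convention for signal-prediction runs.

### Residual feedback

The residual variant trains the network on increments
`d_t = x_t − x_{t−1}` and adds `x_{t−1}` back at prediction time.  A
zero-output network then reduces to the persistence forecast, so the
network only learns a correction to it.  On near-unit-root series this is
never worse than the plain variant on average (asserted over 10 seeds) and
it is exact on a linear ramp, where the increment is constant.

### A structural limit worth knowing

Every neuron is fitted to the *final* target.  If an intermediate quantity
is needed whose correlation with the target is zero — e.g. the factor
`x1·x2` of the four-way product `(x1·x2)(x3·x4)` under a symmetric design —
no layer can construct it exactly: its coefficients are sampling noise of
order 1/√n, and the contamination propagates through later layers.  Depth
still helps on such targets (the criterion roughly halves), but exact
recovery is limited to compositions whose intermediate stages themselves
predict the target.

## Metrics

NRMSE is RMSE divided by the observed range of the *true* signal, the
normalization consistent with reported magnitudes in this literature
(signals spanning thousands of units with NRMSE a few percent).
Cross-correlation is the Pearson correlation of the overlapping segments at
each lag.  Zero-denominator classification scores are reported as 0 and
flagged degenerate rather than raising.  Wall-clock train/test times appear
in reports but are never asserted on.

## Why R² ≈ 0.5 on the synthetic channels

One-step prediction of an AR(2) process can at best explain
1 − var(innovation)/var(signal) of the variance; for the default
coefficients that is ≈ 0.52.  The backtests in `scripts/acceptance.py`
reach R² ≈ 0.50 — essentially the ceiling — so the forecaster is doing its
job even though the absolute number looks far below the high-90s figures
reported for real EMG, whose sample-to-sample correlation is much stronger
than this deliberately noise-dominated generator.

## Problem sizes

The test suite and acceptance script use 10,000-sample recordings for the
headline backtests, 2,000–3,000-sample series for Monte-Carlo contrasts
(20 seeds for peak statistics, 10 for the residual comparison), and
200–1,000-row designs for the recovery studies — sizes at which every
reported quantity is stable across seeds while the whole suite runs in
well under a minute.
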