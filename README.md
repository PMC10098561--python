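# emg-gmdh

Time-domain feature extraction and self-organizing polynomial-network
forecasting for multichannel surface EMG (electromyography) signals.

Surface EMG records the electrical activity of skeletal muscle as a noisy,
band-limited, zero-mean time series; muscle activity shows up as amplitude
bursts, and violent ("aggressive") actions produce systematically higher
peaks than ordinary ("normal") ones.  This package is for signal-processing
and biomedical-ML practitioners who need to (a) turn raw multichannel EMG
into the classical window features used for activity classification, and
(b) forecast a channel one step ahead with a small, self-structuring model
that can run on modest hardware.

## What is inside

- **`signal_io`** — headerless delimited signal text (the common 8-channel
  physical-action dialect) in and out; versioned JSON model files.
- **`synthetic_emg`** — seeded generator of EMG-like signals: amplitude-
  modulated AR(2) noise with Bernoulli-placed bursts, with `normal` and
  `aggressive` regimes; plus AR-series and polynomial regression fixtures.
- **`preprocessing`** — standard / robust / min-max / row-normalizer
  scaling, db4 discrete-wavelet framing, and the supervised transform
  `(x_{t-lag} … x_{t-1}) → x_t`.
- **`features`** — IEMG, MAV, MAV1, RMS, AAC, ZC, SSC, WAMP, WL, SD per
  window per channel.
- **`gmdh_core`** — the GMDH (Group Method of Data Handling) network, and a
  forecasting front-end with an optional residual-feedback variant.
- **`metrics`** — RMSE, NRMSE (range-normalized), R², lagged
  cross-correlation, confusion-matrix scores, and score-report assembly.
- **`cli`** — `emg-gmdh simulate | features | train | predict | evaluate`.

## The model

A GMDH network grows itself from two-input polynomial neurons.  Each neuron
is a partial description of the Kolmogorov–Gabor polynomial, e.g. the
linear-with-covariance form

    f(u, v) = w0 + w1·u + w2·v + w3·u·v,

fitted by (ridge) least squares, `argmin ‖Bw − y‖² + λ‖w‖²`, on a training
subset A of the rows.  Every layer enumerates all unordered pairs of its
inputs (raw lag samples for layer 1, the previous layer's survivors after
that), scores each candidate with an **external criterion** computed on data
the fit did not use — validation MSE on subset B, a two-fit bias term
`mean((ŷ_A − ŷ_B)²)`, or their sum — and keeps only the best K neurons
(select-and-drop).  A layer is accepted when its best criterion improves on
the best so far by more than ε; growth stops when no layer in the last few
improved, or at the depth cap.  The final model is the single best neuron
plus its dependency path.

For forecasting, a univariate series is framed as `lag` past samples →
next sample (default lag 10).  The **residual-feedback** variant trains on
increments `d_t = x_t − x_{t−1}` and adds the last observed sample back at
prediction time, so the network only has to learn a correction to the
persistence baseline — which is both easier and safer when the test segment
drifts outside the training range.

## Worked example

`python examples/forecast_channel.py` trains on the first 5,000 samples of
a synthetic aggressive-regime channel and scores one-step predictions on
the next 5,000:

```
        label  layers     rmse    nrmse  r_squared  train_time_s  test_time_s
   plain GMDH     4.0 4.441419 0.065309   0.503123      1.688631     0.001070
residual GMDH     6.0 4.445118 0.065363   0.502295      1.901119     0.001463
     Averages     5.0 4.443268 0.065336   0.502709      1.794875     0.001267
```

RMSE is in signal units, NRMSE is RMSE divided by the observed range of the
true signal (6.5% here), and R² is the fraction of signal variance the
forecaster explains.  R² ≈ 0.50 is the ceiling for this synthetic channel:
it is an AR(2) process whose innovation noise carries roughly half the
variance, and innovations are unpredictable by construction.  The other
examples (`simulate_signals.py`, `extract_features.py`,
`scale_and_wavelet.py`) walk through generation, feature tables and
scaling/wavelet identities the same way.

The same pipeline from a shell:

```sh
emg-gmdh simulate --regime aggressive --seed 7 --out emg.txt
emg-gmdh features --input emg.txt --out features.csv
emg-gmdh evaluate --input emg.txt --residual --out report.csv
```

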