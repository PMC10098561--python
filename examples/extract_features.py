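"""Window-feature extraction on a synthetic recording.

Cuts an 8-channel signal into non-overlapping 256-sample windows and
computes the 10 time-domain features (IEMG, MAV, MAV1, RMS, AAC, ZC, SSC,
WAMP, WL, SD) per window and channel — the inputs a downstream activity
classifier would consume.
"""

from emg_gmdh import EmgSimConfig, FeatureConfig, extract_features, features_to_frame, simulate_emg

frame = simulate_emg(EmgSimConfig(regime="aggressive", n_samples=2_048, seed=3))
vectors = extract_features(frame, FeatureConfig(window_length=256, window_step=256))
table = features_to_frame(vectors)

print(f"{len(vectors)} windows x {frame.n_channels} channels x 10 features "
      f"= {len(table)} values")
print(table.head(10).to_string(index=False))
print("Each row is one feature of one channel in one window; RMS and IEMG")
print("jump in windows that contain a burst.")
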