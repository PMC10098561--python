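"""Feature scaling and db4 wavelet framing of a signal channel.

Standardizes an 8-channel frame (zero mean, unit variance per channel),
then decomposes one channel into db4 wavelet bands and prints the energy
per band — a compact view of how signal power splits across scales.
"""

import numpy as np

from emg_gmdh import EmgSimConfig, dwt_frames, fit_scaler, simulate_emg, transform

frame = simulate_emg(EmgSimConfig(regime="normal", n_samples=2_048, seed=5))
scaled = transform(fit_scaler("standard", frame), frame)
print("per-channel mean after standardization:",
      np.round(scaled.data.mean(axis=0), 12).tolist())
print("per-channel SD after standardization:",
      np.round(scaled.data.std(axis=0), 12).tolist())

bands = dwt_frames(scaled.channel(0), wavelet="db4", level=4, mode="periodization")
total = sum(float(np.sum(b**2)) for b in bands)
print("\ndb4 band energies (coarse approximation first, then finer details):")
for name, band in zip(["A4", "D4", "D3", "D2", "D1"], bands):
    energy = float(np.sum(band**2))
    print(f"  {name}: {100 * energy / total:5.1f}% of energy in {band.size} coefficients")
print("The AR(2)-shaped signal concentrates energy in the mid-scale bands;")
print("under periodization the band energies sum to the signal energy exactly.")
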