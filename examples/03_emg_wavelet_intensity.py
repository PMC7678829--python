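"""Time-resolved EMG intensity through the 11-wavelet filter bank.

Generates a burst of band-limited noise with a low-frequency motion artifact,
decomposes it with the non-linearly scaled wavelet bank (6.90-395.44 Hz) and
shows that excluding the first wavelet suppresses the artifact while the
burst is localised correctly in time.
"""

import numpy as np

from myowave import build_bank, center_frequencies, generate_emg_trace, intensity

trace = generate_emg_trace([(0.8, 1.2)], duration_s=2.0, artifact_hz=4.0,
                           artifact_amplitude=0.5, seed=6)
bank = build_bank(trace.sampling_rate_hz, len(trace.values))
out = intensity(trace, bank)

cfs = center_frequencies()
print("center frequencies (Hz):", np.round(cfs, 2))
t_peak = out.times[np.argmax(out.total_intensity)]
print(f"total-intensity peak at  t = {t_peak:.3f} s (burst: 0.8-1.2 s)")
b0 = out.band_intensities[0].mean()
print(f"band-0 mean intensity:   {b0:.4f} (motion artifact)")
print(f"total mean intensity:    {out.total_intensity.mean():.4f} "
      "(band 0 excluded)")
# The 4 Hz artifact loads the first wavelet only; the total intensity, which
# sums wavelets 2-11, peaks inside the muscle burst.
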