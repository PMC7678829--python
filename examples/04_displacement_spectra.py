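"""Power-frequency statistics of landmark transverse displacement.

Builds a displacement signal with a known low-frequency gait component plus a
9 Hz oscillation, high-passes it at the stride frequency, and extracts the
two summary statistics: peak power (mm^2) and the cumulative frequency CF50
at which the area under the power-frequency curve reaches half its total.
"""

import numpy as np

from myowave.spectra import DisplacementSet, highpass_stride, power_spectrum

frame_rate = 80.0
t = np.arange(240) / frame_rate          # a 3 s stance-like window
gait = 2.0 * np.sin(2 * np.pi * 1.4 * t)        # stride-frequency motion
osc = 1.2 * np.sin(2 * np.pi * 9.0 * t + 0.5)   # tissue oscillation
displ = DisplacementSet(np.tile(gait + osc, (19, 1)), frame_rate, np.zeros(19))

filtered = highpass_stride(displ, stride_frequency_hz=2.4)
summary = power_spectrum(filtered.displacement_mm[9], frame_rate)

print(f"peak power:           {summary.peak_power_mm2:.3f} mm^2 "
      f"(pure 1.2 mm sinusoid carries {1.2**2 / 2:.3f} mm^2)")
print(f"cumulative frequency: {summary.cumulative_frequency_hz:.2f} Hz "
      "(injected oscillation: 9 Hz)")
# After the stride-frequency high-pass the gait component is gone, so half
# the remaining signal power accumulates right at the injected 9 Hz.
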