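"""Estimate the impact input frequency from a vertical GRF trace.

Generates a running ground-reaction-force trace whose impact transient
oscillates at a known 15 Hz, then recovers that frequency from the interval
between maximal rate of force development and the impact force peak
(quarter-wave convention: that interval is a quarter oscillation).
"""

from myowave import analyze_force_trace, generate_force_trace

trace = generate_force_trace(gait="running", impact_frequency_hz=15.0,
                             stance_duration_s=0.30, n_stances=4, seed=3)
table = analyze_force_trace(trace, prefiltered=True, threshold_N=5.0)
print(table.to_string(index=False))
print(f"\ninjected impact frequency: {trace.truth.impact_frequency_hz} Hz")
print(f"mean estimate:             {table.input_frequency_hz.mean():.2f} Hz")
# Each stance yields one estimate; deviations from 15 Hz reflect only the
# 0.5 ms sample quantisation of the 2 kHz force plate grid.
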