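# myowave

Quantifying **in vivo transverse muscle oscillations** from B-mode ultrasound
during walking and running.

Foot–ground impacts during gait act as input signals that the body must damp,
and skeletal muscle "wobble" is one of the proposed damping mechanisms.
`myowave` implements a complete, tested pipeline for measuring these
oscillations directly in the muscle rather than at the skin surface:

1. **Segmentation** — an active shape model (ASM) tracks 19 evenly spaced
   landmarks (32 px apart) on the superficial and deep aponeuroses of the
   soleus through B-mode image sequences (~80 frames/s, 60 × 50 mm field of
   view). A point distribution model `x = x̄ + P b` (modes `P`, coefficients
   clamped to ±3√λᵢ) is combined with per-landmark Gaussian models of the
   normalised intensity-gradient profile along the boundary normal, fitted
   coarse-to-fine by minimising the Mahalanobis distance
   `(g − ḡ)ᵀ S_g⁻¹ (g − ḡ)`. Each frame's solution initialises the next.
2. **Impact input frequency** — from the vertical ground reaction force
   (2000 Hz), the interval Δt between maximal rate of force development and
   the impact force maximum spans a quarter oscillation of the impact
   signal, so `f_input = 1/(4Δt)` (the literal reciprocal `1/Δt` is also
   available).
3. **Oscillation spectra** — landmark rows become transverse displacement in
   mm relative to a quiet-standing reference (positive = toward the skin),
   are high-pass filtered at the stride frequency (4th-order zero-phase
   Butterworth; condition cutoffs 1.3–3.1 Hz), and Fourier-analysed over
   0–40 Hz. Per landmark the pipeline reports the **peak power** (mm²) and
   the **cumulative frequency CF50**: the frequency below which half the
   area under the power–frequency curve accumulates.
4. **EMG intensity** — surface EMG is decomposed by a bank of 11
   non-linearly scaled wavelets, `cf_j = (1/0.3)(j + 1.45)^1.959`, spanning
   6.90–395.44 Hz; the first wavelet is excluded from the total intensity to
   suppress motion artifact.
5. **Statistics** — one- and two-way repeated-measures ANOVAs (image region
   × locomotion condition) with Bonferroni-corrected post-hoc tests, and
   linear/quadratic fits of the oscillation metrics against input frequency
   with r².

Because in vivo recordings of this kind are not freely available, the
package ships a first-class synthetic-data module: ultrasound scenes with
speckle and exactly known boundary motion, GRF traces with exactly known
impact timing, and amplitude-modulated EMG — so every stage of the pipeline
has a recoverable ground truth, and the whole study design can be simulated
end-to-end.

## Worked example

Estimate the impact input frequency from a synthetic running trace with a
known 15 Hz transient (`examples/02_input_frequency_from_grf.py`):

```python
from myowave import analyze_force_trace, generate_force_trace

trace = generate_force_trace(gait="running", impact_frequency_hz=15.0,
                             stance_duration_s=0.30, n_stances=4, seed=3)
print(analyze_force_trace(trace, prefiltered=True, threshold_N=5.0))
```

```
 stance_index  t_max_rfd  t_peak_force  delta_t_s  input_frequency_hz   convention
            0     0.1005        0.1165      0.016              15.625 quarter_wave
            ...
```

Each stance yields Δt = 16 ms, i.e. 15.6 Hz — the injected 15 Hz up to the
0.5 ms sample quantisation of the 2 kHz force grid. The spectral side
(`examples/04_displacement_spectra.py`) recovers an injected 9 Hz, 1.2 mm
oscillation as:

```
peak power:           0.708 mm^2 (pure 1.2 mm sinusoid carries 0.720 mm^2)
cumulative frequency: 9.00 Hz (injected oscillation: 9 Hz)
```

The scripts in `examples/` cover each capability: segmentation
(`01`), kinetics (`02`), EMG intensity (`03`), spectra (`04`) and the full
simulated study with ANOVAs and trend fits (`05`).

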