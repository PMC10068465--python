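# rippleloc

Ripple-band (80–250 Hz) high-frequency oscillations on MEG are a candidate
biomarker of the epileptogenic zone. `rippleloc` is a toolkit for the full
analysis chain used in ripple-based presurgical evaluation:

1. **Preprocessing** — DFT line-noise removal, z-score artifact-channel
   rejection, zero-phase ripple-band filtering.
2. **Automatic ripple detection** — per 0.6 s window, db4 wavelet denoising
   and a dynamic threshold from the *peak-points distribution curve* (PPDC):
   peaks of the rectified band-passed trace are ranked from highest to
   lowest, a line is fitted to the 30%–60% rank segment, and the threshold is
   that line extrapolated to the top rank, raised 5%; runs of ≥ 4 consecutive
   supra-threshold peaks with 80–250 Hz spacing and a smoothly rising/falling
   envelope become ripple events.
3. **Scalp-level features** — ripple rates per 10 min, four-lobe channel
   distribution (78/78/78/72), omega spatial complexity
   Ω = exp(−Σᵢ λ′ᵢ ln λ′ᵢ) over normalized covariance eigenvalues of 0.3 s
   ripple windows, and coherence-graph clustering coefficients
   C_k = 2e/(n(n−1)) standardized as C_s = (C_k − C_A)/C_A at a 0.7
   magnitude-squared-coherence threshold.
4. **Source localization** — ripple windows stacked into a channels × time ×
   events tensor, denoised by truncated Tucker decomposition
   (A ≈ G ×₁ U₁ ×₂ U₂ ×₃ U₃, HOSVD + HOOI), then localized per event with an
   LCMV beamformer (unit-noise-gain power (lᵀC⁻¹l)/(lᵀC⁻²l) per grid point).
5. **Source-level network** — beamformed grid series averaged over a 90-ROI
   parcellation, ROI×ROI coherence C_xy = |S_xy|²/(S_xx S_yy) averaged over
   ripple windows and over the band, betweenness-centrality ranking of the
   thresholded graph, and an augmented in-resection score that rescues events
   whose peak ROI is both a top-10 network hub and adjacent to the resection.

A synthetic-data module (`rippleloc.synthetic`) generates ground-truth
recordings — pink/white sensor noise, Hann-windowed ripple bursts, dipolar
sources through a toy lead field, Poisson cohorts, and planted-hub
propagation networks — so every stage is testable without patient data.

## Worked example

```python
import numpy as np
from rippleloc import (SimulationSpec, RipplePlanEntry, simulate_recording,
                       detect_ripples, ripple_count_rate)

plan = [RipplePlanEntry(channel=i % 4, onset=2.0 + 3.0 * i,
                        freq=150.0, n_cycles=8, amplitude=5.0)
        for i in range(10)]
spec = SimulationSpec(duration=35.0, n_channels=4, fs=1000.0,
                      ripple_plan=plan, seed=1)
rec, truth = simulate_recording(spec)
events = detect_ripples(rec)
print(len(events), "events,",
      round(ripple_count_rate(events, rec.duration), 2), "per 10 min")
print(round(events[0].onset, 3), "s,", round(events[0].mean_freq, 1), "Hz")
```

prints

```
10 events, 171.43 per 10 min
2.015 s, 152.2 Hz
```

— all ten injected 150 Hz bursts are recovered (the rate is high because the
example packs ten bursts into 35 s), the first at 2.015 s against a true
onset of 2.0 s, with its frequency estimated at 152.2 Hz.

The same chain runs from the shell:

```bash
rippleloc simulate --out rec.tsv --channels 64 --duration 35 --n-bursts 10 --seed 1
rippleloc detect --input rec.tsv --out events.tsv
rippleloc forward --out fwd.tsv --channels 64 --sources 96 --seed 3
rippleloc localize --input rec.tsv --events events.tsv --forward fwd.tsv \
    --method tucker-lcmv --out estimates.tsv
rippleloc network --input rec.tsv --events events.tsv --forward fwd.tsv \
    --threshold 0.7 --top 10 --out network.json
rippleloc cohort --per-group 3 --duration 60 --channels 30 --out cohort_out
```

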