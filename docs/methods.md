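# Methods

This note documents the models, the numerical choices, and the synthetic
conditions under which the toolkit is validated. It is the place to look when
a default needs changing or a test result needs interpreting.

## Signal model and preprocessing

A recording is a channels × samples matrix at sampling rate `fs` (defaults
emulate a 306-channel whole-head array at 1000 Hz; any channel count works).
Channels map onto four lobes — frontal/temporal/parietal/occipital, split
78/78/78/72 for 306 channels and proportionally otherwise.

*Line noise* is removed by least-squares regression of sine/cosine pairs at
the line frequency and its harmonics over the whole record (the classic DFT
filter). The default line frequency is 50 Hz; it is a configuration value,
not a property of the method.

*Artifact channels* are flagged when more than `frac_limit` (default 0.1%) of
a channel's samples exceed `z_abs_limit` (default 5) standard deviations of
its own distribution; zero-variance (dead) channels are flagged rather than
crashing the z-scoring. The rule is deterministic, idempotent, and computed
from the raw data so it does not depend on what was flagged before.

*Ripple-band filtering* uses a zero-phase Hamming-window FIR (length ≈ 4·fs/16
taps, applied forward–backward). Cutoffs sit ~10% outside the nominal
80–250 Hz band so the band edges lie in the flat passband while 64 Hz and
300 Hz (band ± 20%) fall ≥ 40 dB down.

## Ripple detection

Per channel, 0.6 s windows slide with 50% overlap. Each raw window is
wavelet-denoised and then band-passed — in that order, because the universal
wavelet threshold needs the broadband noise level, which band-passing first
would delete.

**Denoising.** db4 decomposition to level 4; noise scale σ = MAD/0.6745 using
the *minimum* MAD across detail levels (for white noise every level carries
the same σ, whereas narrowband content can only inflate some levels, so the
minimum resists in-band leakage); universal threshold σ√(2 ln N), applied
*hard*. Soft thresholding was rejected: its shrinkage bias on every retained
coefficient (≈ #retained × thr²) exceeds the removed noise variance for
dense oscillations at any amplitude, so it can never reduce the MSE of a
sustained in-band tone; hard thresholding keeps supra-threshold oscillation
coefficients intact and wins on burst-shaped signals.

**Peaks.** Local maxima of the rectified trace with a minimum spacing of one
250 Hz period (4 ms). The spacing floor removes the half-cycle double peaks
of rectification, so inter-peak intervals of a true ripple fall in
[4, 12.5] ms across the whole band. Event frequency is estimated from zero
crossings over the peak train's extent (interval-based estimates are ambiguous
between half- and full-period readings below 125 Hz).

**Threshold.** The PPDC ranks the window's peak amplitudes from highest to
lowest; a least-squares line over the 30%–60% rank segment is extrapolated to
rank 0 and multiplied by 1.05. This threshold is exactly scale-equivariant:
scaling the window by k scales it by k. Because a purely relative per-window
threshold always marks the top ~15% of peaks — even in pure noise — peaks
must additionally clear an *RMS floor* of 10× the channel's median per-window
band RMS (a robust background estimate; the multiplier was chosen from the
measured separation between noise-window peaks, which stay below ~19× the
median RMS even in the extreme tail, and 5×-RMS burst peaks, whose fourth-
largest peak sits near 33×). The floor scales with the recording, so global
amplitude scale still cannot change any detection decision.

**Events.** Runs of ≥ 4 consecutive supra-threshold peaks whose spacing stays
within one 80 Hz period and whose amplitude envelope is unimodal (grown
around the run maximum with 20% per-step tolerance) become events; events
from overlapping windows merge when they share > 50% of the shorter duration,
deduplicating peaks closer than the 4 ms peak spacing.

## Scalp features

*Lobe distribution*: the share of ripple-carrying channels per lobe (each
channel counted once).

*Omega spatial complexity*: eigenvalues λᵢ of the channel covariance of a
mean-removed 0.3 s window, normalized to λ′ᵢ; Ω = exp(−Σ λ′ᵢ ln λ′ᵢ) ranges
from 1 (one synchronized field pattern) to m (m independent channels) and is
invariant to global scaling and channel permutation.

*Coherence clustering*: magnitude-squared coherence
C_xy(f) = |S_xy|²/(S_xx S_yy) with Hann-tapered cross-spectra averaged over
all of a subject's 0.3 s ripple windows, then averaged over 80–250 Hz. A
single window makes coherence identically 1, so at least two windows are
required; a Welch-style split of a lone window into three half-overlapping
sub-windows is available as a fallback. The graph uses a strict > 0.7 edge
rule and is binarized (the edge-count formula C_k = 2e/(n(n−1)) requires
binary edges; a triangle-intensity weighted variant is available behind a
flag). Nodes with < 2 neighbors get C_k = 0. The standardized coefficient
C_s = (C_k − C_A)/C_A is undefined when the network average C_A is 0.

*Group statistics*: one-way ANOVA with Bonferroni-multiplied pairwise Welch
t-tests (capped at 1), significance at p < 0.05.

## Tucker denoising and LCMV

Ripple windows (0.3 s, centered on each event, zero-padded at the record
edges) stack into an order-3 tensor, channels × time × events; a single event
gives a singleton third mode, reducing Tucker to the matrix SVD case.

Ranks default to the smallest per-mode counts retaining 95% of the
mode-unfolded singular-value energy. HOSVD initializes the factors; HOOI
(alternating SVDs of the projected unfoldings) refines them until the fit
changes by < 1e-6 or 50 iterations; the fit (retained Frobenius energy) is
nondecreasing over iterations. Because per-mode 95% rules can compound, the
weakest mode's rank is escalated until the joint fit reaches the target
minus 0.02. Order-2 input reproduces the truncated SVD to machine precision.
Denoising helps most at moderate noise; at very low noise the energy rule can
truncate genuinely weak signal directions, and at extreme noise it retains
mostly noise dimensions — the paired localization test therefore asserts the
denoised error is no worse, not strictly better.

The LCMV beamformer regularizes the window covariance as C + λI with
λ = 5% of the mean sensor variance. Power per grid point is the
unit-noise-gain (neural activity index) form (lᵀC⁻¹l)/(lᵀC⁻²l), which is
flat under isotropic covariance (no depth bias) and scales as k² when the
data scale by k, leaving the argmax unchanged. Free-orientation (3-column)
lead fields use the largest generalized eigenvalue of the corresponding 3×3
matrices. The grid argmax maps through the parcellation to the event's ROI;
the in-resection fraction is the share of events whose ROI lies in the mask.

## Source-level network

Grid time courses come from unit-gain LCMV filters computed, by default, from
the pooled covariance of all ripple windows — per-window filters at ~300
samples are dominated by weight-estimation noise, which in testing destroyed
genuine source-level coherence (per-window filters remain available). Grid
series average within each of the 90 ROI labels (empty ROIs yield flagged
zero series). ROI coherence follows the scalp formula over ripple windows;
betweenness centrality (pair-normalized shortest-path form) is computed on
the > 0.7 binarized graph, with ties in the descending ranking broken by
label order and flagged when they cross the top-k boundary; a
distance = 1/coherence weighted variant sits behind a flag.

**Combined localization.** How network hubs should augment localization is
genuinely open; the rule here is an OR-combination: an event is in-resection
if its beamformer ROI is in the mask, *or* if that ROI is simultaneously a
top-10 betweenness hub and resection-adjacent (centroid within 1.5× the
median nearest-centroid spacing of a mask ROI). The combined fraction is
≥ the plain fraction by construction; the rule is config-replaceable.

## Synthetic data: what it emulates, and what it does not

*Recordings*: pink (1/f-shaped) or white Gaussian sensor noise with
Hann-windowed sinusoidal bursts at stated channels/onsets/frequencies, burst
amplitude quoted relative to the channel background RMS. Real ripple
morphology (asymmetric envelopes, superimposed spikes), non-stationary
background, and sensor-type heterogeneity are not modeled — detector results
here bound performance on clean injections, not on clinical recordings.

*Cohorts*: per-subject event counts are Poisson at the group rate (events per
10 min, defaults 5.4/9.3/3.5 for the three 21-subject groups), with uniform
channels, onsets, and frequencies in 100–220 Hz. Cohort-level statistics are
validated at the count level (`waveforms=False`); waveform-level detection
fidelity is validated separately because simulating 63 ten-minute 306-channel
subjects per replicate is far beyond desk scale. Validation problem sizes
throughout (4–30 channels, 20–60 s recordings, 64-sensor/96-point forward
models) are chosen so the full suite runs in minutes; all operations accept
full-size inputs.

*Forward models*: `spherical-toy` places sensors on a 1.2-radius sphere
(Fibonacci lattice) over a regular source lattice in the unit ball with
point-magnetic-dipole gains projected on sensor normals; `random-orthogonal`
uses QR-orthonormalized Gaussian columns. The 90-ROI parcellation assigns
each grid point to the nearest of 90 centroids drawn from the grid, so every
label is nonempty. No tissue conductivity, no MRI: localization errors are
meaningful in units of grid spacing only.

*Planted hub*: a hub grid point (its ROI is the resection) drives four
spatial neighbours in distinct ROIs down a chain; each link is a 6 ms-delayed
copy of its predecessor mixed with fresh ripple-band noise (coupling 0.88).
The 6 ms delay sits at the first zero of the ripple-band autocorrelation, so
simultaneously active sources are time-uncorrelated — an LCMV prerequisite:
zero-lag-correlated sources partially cancel and localization collapses. The
delay leaves magnitude coherence untouched, giving neighbor coherence just
above 0.7 and two-step coherence below it: a path graph whose interior
relays carry the betweenness. Each event has one dominant generator (the hub
with probability 0.5, else a relay at amplitude ratio 1:0.6, sensor SNR 40),
so relays capture propagated ripples that localize just outside the
single-ROI resection and are exactly the events the top-10/adjacent rescue
rule can recover. Broadband (not sinusoidal) carriers are essential: the
coherence is averaged over all band bins, and a narrowband carrier occupies
too few bins to lift the band average over the edge threshold.

## Known limitations

- The RMS floor assumes ripples are rare (median window RMS ≈ background);
  recordings where most windows contain events would raise the floor.
- Coherence averaged over few ripple windows is biased upward by ≈ 1/n_seg.
- Tucker rank selection by mode-wise energy has no optimality guarantee; at
  very low SNR it retains noise dimensions and denoising degenerates toward
  the identity (or worse for localization — see the paired test).
- The toy forward model's gains are not physiological; absolute localization
  accuracy on real MEG is outside what these tests can show.
- EDF files are read (via mne) but not written; FIF and tsv-matrix cover
  export.
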