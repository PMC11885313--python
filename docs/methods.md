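# Methods

Models, parameter choices and numerical details behind `strokesig`. Units
are stated everywhere; defaults live in the function signatures and in
`SyntheticConfig`.

## 1. Signal model

A recorded channel is modeled as aperiodic background plus oscillations plus
task-locked structure:

```
S(f) = A / f^β + floor + Σ_k G_k(f; f_k, σ_k, h_k)
```

with `A` the aperiodic amplitude (V²·Hz^(β−1)), `β` the aperiodic exponent,
`floor` a flat wideband noise floor (V²/Hz), and Gaussian peaks `G_k`
(center `f_k` Hz, width `σ_k` Hz, height `h_k` V²/Hz) for oscillations.
Task-locked high-gamma appears as a multiplicative envelope on the
band-limited component of the signal around each movement event;
phase–amplitude coupling as a high-gamma envelope term
`(1−s) + s·(1+cos φ_δ)/2` driven by the instantaneous delta phase `φ_δ`,
with coupling strength `s ∈ [0, 1]`.

Spiking is an inhomogeneous Poisson process on a 10-ms rate grid. Responsive
channels ramp their rate linearly from baseline to `pre_close_gain ×`
baseline over the 1 s before each closing onset and drop to 0.3× baseline
for 0.5 s after it; cosine-tuned channels follow
`r(θ) = r₀·g·(1 + d·cos(θ − θ_pref))` during each reach.

## 2. Preprocessing

* **Band-pass**: Butterworth, order 8, 0.5–1000 Hz, applied zero-phase as a
  single second-order-section cascade (`sosfiltfilt`). The 0.5 Hz corner
  rings for several seconds at record edges; analyses that quantify
  amplitudes do so away from edges (the tests measure steady-state
  attenuation on the central third of 30-s tones). When the sampling rate
  makes 1000 Hz ≥ Nyquist, the pipelines clip the upper edge to `0.45·fs`.
* **Notch**: 60 Hz, IIR band-stop of half-width 1 Hz, order 4 per harmonic;
  `n_harmonics=1` removes 60 Hz only, `3` removes 60/120/180 Hz.
* **Sliding z-score**: causal, trailing 30-s window, computed with cumulative
  sums (O(n)). The first 30 s reuse the first complete window's statistics
  so the output has no warm-up NaNs. Standard deviations are floored at
  `1e-12 ×` the signal scale to avoid division blow-ups on silent channels.
* **Stream alignment**: FFT cross-correlation with parabolic sub-sample peak
  refinement. Significance uses a block-shuffled surrogate null (blocks of
  ~1000 samples, 200 surrogates, α = 0.01): circularly shifting a sparse
  pulse train partially preserves alignment under linear correlation, so a
  circular-shift null is anticonservative there; block shuffling destroys
  the long-range structure while keeping the local waveform statistics.

## 3. Spectral estimation and IRASA

Welch PSDs use Hann tapers, 50% overlap, constant detrend, and an `nfft`
chosen so the native resolution matches the requested frequency increment.
The decoder feature is the mean over channels and sub-bands of sliding
1-s-window band power in 100–500 Hz.

IRASA resamples the signal by factors `h ∈ {1.1, 1.15, …, 1.9}` and their
reciprocals (polyphase resampling of the rational approximation
`round(100·h)/100`), computes Welch spectra of each pair with segment length
scaled by `h` so they share a frequency grid, and takes the geometric mean:
a power law `C·f^(−β)` maps to `C·h^(1−β)·f^(−β)` and `C·h^(β−1)·f^(−β)`
under the pair, so the geometric mean is exactly `C·f^(−β)` while shifted
oscillatory peaks average out. The median across factors is the aperiodic
estimate; oscillatory = total − aperiodic, deliberately *not* clipped at
zero (a negative residue is informative about misfit). `β` comes from an
ordinary least-squares fit of `log P` on `log f` over 1–30 Hz; the lower
edge avoids the band-pass corner and edge bins, the upper edge stays below
the line-noise notch region.

Two internal numerical choices differ from the plain Welch operation:

* **Blackman taper inside IRASA.** With steep spectra (β ≈ 3) the strong
  0.25–0.5 Hz content leaks through Hann sidelobes into the lowest octave of
  the down-resampled spectra and biases the split by more than 10%.
  Blackman's −58 dB sidelobes remove this; the public `welch_psd` keeps the
  conventional Hann.
* **0.5 Hz output grid.** The 4-s analysis windows give a 0.25 Hz native
  grid; the decomposition is reported on a 0.5 Hz grid, each point averaging
  the native bins within ± half an increment. This halves per-bin estimator
  variance and matches the reporting resolution used elsewhere.

Validation: on pure `1/f^β` noise the fitted exponent has mean absolute
error ≤ 0.1 for β ∈ {1, 2, 3} and the oscillatory residue stays below 10%
of the aperiodic component for f ≥ 1 Hz (see `tests/test_acceptance.py`).

## 4. Movement-event rules

The aperture trace (percent open, 20 Hz) is segmented into monotone sweeps
with a 1%-per-sample deadband; a single sub-deadband sample does not split a
sweep, and consecutive same-direction sweeps form an episode. A **closing**
episode is valid iff it starts at ≥ 80% aperture and some sweep reaches
≤ 30%; its onset is the start of the *last* qualifying sweep, so a
pause-and-resume closing is timed from the resume. Openings mirror this
(start ≤ 30%, reach ≥ 80% — full-open within 0.5% counts). Each event row
records which clause admitted it (`reached_full_close` /
`reached_30pct_closed` and mirrors). Stalled movements (never reach the far
threshold) and movements starting from mid-range are rejected. The rule
tests plant every clause and require recall 1.0, zero false positives, and
onsets within one kinematic sample (50 ms).

## 5. Spiking statistics

* **Binned rates**: 100-ms windows stepped by 20 ms over −1…+1 s around each
  onset.
* **Responsiveness**: per channel and window, a Kruskal–Wallis test of
  closing-epoch vs opening-epoch rates at α = 0.01 (`scipy.stats.kruskal`;
  an all-tied window is defined as H = 0, p = 1). The characterization
  window is the one flagging the most channels. On null data (identical
  Poisson processes in both conditions) the empirical flag rate stays
  within [0.005, 0.02] of the nominal 0.01 across > 10 000 window tests.
  Benjamini–Hochberg correction is available but off by default, matching
  the per-window α convention.
* **NLIFR**: causal 300-ms-window rates on a 20-ms grid through a leaky
  integrator (`τ = 0.3 s`), max-normalized per channel over −0.5…+1.0 s
  (76 points).
* **Neuromodulation index**: variance (ddof = 1) of ten 50-ms bin rates per
  0.5-s block, averaged over blocks; the top-8 channels feed the threshold
  decoder. Ties break toward the lower channel index for determinism.

## 6. Phase–amplitude coupling

Phase band 1–4 Hz, amplitude band 70–450 Hz (order-4 Butterworth,
zero-phase), Hilbert transform, phase in degrees ∈ [−180, 180). Amplitudes
are averaged in N = 20 bins of 18°, normalized to a distribution `p`, and

```
MI = (log N − H(p)) / log N.
```

MI is exactly 0 for uniform `p` and exactly 1 when all amplitude sits in one
bin (verified to 1e-12). On synthetic coupling the measured MI is strictly
increasing in the injected strength for every tested seed. Windows shorter
than two cycles of the phase band's low edge are flagged low-confidence.

## 7. Decoding

* **Threshold grasp decoder**: a two-state machine starting "open"; emits
  `close` when the band-power feature exceeds 10 while open and `open` when
  the feature re-enters [0.5, 3.0] while closed; anything else is
  hysteresis. The defaults are calibrated analytically against the
  generator: with a 1.5 V²/Hz noise floor the baseline feature sits near
  1.75 (inside the open range) and an event-locked gamma gain of 8 drives
  it to ≈ 13 (above the close threshold).
* **Direction classification**: per-trial spike-count features over
  −0.5…+1.0 s around movement appearance, linear SVM (C = 1) or kNN (k = 3),
  2 training trials per direction, 50 stratified resamples. Metrics are
  macro one-vs-rest accuracy, precision, recall, specificity and F1
  (zero-denominator classes contribute 0).
* **Controls**: label permutation (500 shuffles, re-shuffled each iteration)
  must land at the 12.5% 8-class chance level — the acceptance test requires
  the mean accuracy within the 95% binomial interval of p = 1/8 at
  500 × 8 predictions; random 20-channel subsets (100 draws) quantify how
  distributed the information is.

## 8. What the generator does and does not emulate

It emulates: `1/f^β` backgrounds with per-array exponents, oscillatory
peaks, event-locked broadband gamma, delta–gamma coupling, Poisson spiking
with pre-movement ramps, post-movement suppression, coincident multi-channel
bursts, cosine direction tuning, kinematic aperture traces with
pause/stall/low-start distractors, shared sync pulse streams with a
configurable inter-stream lag, and bit-identical reproducibility from a
single seed.

It does not emulate: spike waveforms or sorting noise, electrode drift or
impedance changes, cross-channel correlated noise, artifacts (motion, line
transients), refractory periods, or non-Poisson spike-count dispersion. The
aperture model is piecewise-linear with additive noise, not biomechanical.

Problem sizes in tests and examples (channel counts, durations, event
counts) are the package's own choices, picked so each property is testable
in seconds while keeping enough samples for the statistics involved.

## 9. Limitations

* The z-score and NLIFR are causal, but the filters are zero-phase; the
  package is an *offline* analysis chain, not a real-time decoder.
* IRASA assumes the aperiodic part is a single power law over the analysis
  band; knees or multiple regimes bias `β`.
* The KW responsiveness test treats windows independently; the
  characterization-window selection is a maximum over correlated tests and
  its family-wise behavior is only checked empirically.
* The permutation control shares the train/test resampling scheme with the
  original experiment; it calibrates chance level, not overfitting of the
  feature-extraction choices.
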