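# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what the synthetic sessions do and do not emulate.

## Behavioral scoring

EMG envelopes are the absolute value of the signal passed through a causal
exponential moving average with per-sample factor `exp(−1/(fs·τ))` — the
discrete analogue of a first-order RC smoother, chosen to emulate the
"smooth" semantics of common acquisition software. The twitch path uses
τ = 1 ms (preserving burst onsets so the event time is the first
supra-threshold sample), the wake path τ = 10 ms.

Sleep/wake dichotomization has no published numeric recipe, so the package
uses a deterministic one: the threshold is the midpoint of the envelope's
20th and 80th percentiles, applied with ±10 % hysteresis; runs shorter than
5 s are merged into their neighbors; an envelope whose 80th/20th percentile
ratio is below 1.5 is declared unscorable rather than guessed at. "Baseline"
for the 3× twitch threshold is the median envelope during active-sleep
atonia — the median is robust to the bursts being detected. The wake
baseline is computed per session (not per bout), iteratively once: a
provisional median sets a provisional 5× threshold whose supra-threshold
runs are excluded before the final median.

A wake-movement *trigger* is a supra-threshold run of ≥ 300 ms preceded by
at least 1 s of sub-threshold tone (the first movement of a movement bout);
all sustained runs are returned as scored movements. The 1 s quiescence
quantifies "preceded by a period of low tone", which has no published
duration. With this reading, per-session trigger counts land in the
observed 60–80 range, whereas one trigger per sleep–wake bout would yield
only ~20.

## Response models and classification

PSTHs use a 2 s window *centered* on the event ([−1, +1) s, 10 ms bins,
200 bins): responses begin up to ~100 ms before the triggering twitch
(nearby muscles twitch in volleys), so pre-event bins carry signal.

Both models are fit by bounded trust-region least squares
(`scipy.optimize.curve_fit`) with bounds BL, R_max ∈ [0, ∞) (the models
describe excitatory responses; inhibited units are out of scope),
t_max ∈ [−0.5, 0.75] s, c ∈ [0.005, 0.5] s, λ ∈ [0.5, 200] s⁻¹.
Initialization is a deterministic multi-start — t_max at the peak bin, BL at
the 10th-percentile rate, R_max at peak − BL, c ∈ {0.02, 0.05, 0.15} s
(crossed with λ ∈ {2, 10, 50} s⁻¹ for the asymmetric model) — and the start
with the lowest SSE wins, so fitting is bit-for-bit reproducible with no
random state. Tests hold the fitted SSE to within 1 % of an independent
brute-force grid search (the amplitude pair (BL, R_max) is linear in the
model and solved in closed form per grid shape).

`r²_adj = 1 − ((n−1)/(n−p))·SSE/SST` with n = 200 and p = 4 (Gaussian) or
5 (Gaussian-exponential). Degenerate cases (all-zero PSTH, SST = 0) report
r²_adj = 0 with a flag, so they can never classify as responsive.
Classification is strict (`>` 0.35) per movement type; at exactly 0.35 a
unit is unresponsive. `HWHH = √(2 ln 2)·c` follows from solving
`exp(−x²/2c²) = 1/2`. Population summaries report both the three exclusive
responsive classes and the inclusive "twitch-responsive" convention
(exclusive-twitch + dual), which is the convention behind quoted
percentages such as 73 % at P11 vs 24 % at P12.

In the published fit tables the wake-model λ column is printed in seconds
(0.17–0.40); as a rate it would imply multi-second decays inconsistent with
the plotted responses, so when seeding *simulator* defaults those values are
interpreted as decay time constants (kernel rate = 1/value). The fitted
model itself treats λ as a rate with `t_½ = ln 2/λ`, exactly as defined.

## Trial reliability

The response window is where the fitted model crosses half of its maximum
response (BL + R_max/2): `t_max ± HWHH` for the Gaussian and
`[t_max − HWHH, t_max + t_½]` for the Gaussian-exponential. Half-maximum is
parameter-free and reduces naturally to the model's own width parameters.
Baseline expectation uses the *fitted* BL (not an empirical pre-event rate).
Events with less than 2 s of prior recording are dropped (with the count
reported), because the matched baseline window starts 2 s before the
movement. All count comparisons are strict. When every baseline window
exceeds expectation (P_BL = 1) the correction is undefined and reported as
missing rather than clamped.

## Shift predictor

Reference spikes are those within ±200 ms of an event (symmetric, matching
the pre-trigger activity above; each spike is attributed once, to its
nearest event). The raw correlogram pairs reference and partner activity
around the *same* event; the shift predictor averages over all ordered
noncongruent event pairings, normalized per reference event — i.e. the sum
over reference events of the mean over the (n−1) noncongruent partners —
so that `corrected = raw − predictor` cancels pure stimulus locking exactly
in expectation. The exact all-pairs computation is the default; a seeded
subsample (≥ 200 pairings) is available for sessions where n² pairings is
prohibitive, and is the only stochastic element in the analysis path.
Confidence bands treat each predictor bin as Poisson (σ = √count) and are
two-sided at p = 0.01 (z ≈ 2.576); sums across pairs recombine bands as
z·√(Σ counts). Peak lag is the maximum significant corrected bin, ties
breaking toward the smallest |lag|.

## Evoked potentials and CSD

Raw laminar waveforms are exponentially smoothed (τ = 1 ms) and decimated
to 1 kHz. Evoked potentials average event-aligned segments on
[−0.25, +0.75) s. The CSD is the negated second spatial difference
(sinks negative — both sign convention and boundary handling are stated
because neither is universal), with Vaknin padding (end sites duplicated)
to cover all 16 sites, then cubic interpolation to 10 µm. Conductivity is
omitted; maps are in arbitrary units. Note the boundary rows of a
depth-linear potential are not zero under duplication padding; the
linear-in-depth ⇒ zero-CSD identity holds for the interior rows, which is
what the tests assert. Restricting P8 analyses to periods where twitches
clearly trigger LFP events is exposed as a user-supplied event subset, not
an automatic detector, because no objective criterion for "clearly
triggered" exists.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, with
defaults pinned to the observed session scale:

- **States**: alternating active-sleep/wake bouts, lengths 5 s + exponential
  with mean 60 s (AS) and 30 s (wake) — AS fraction 2/3. Bout-length laws
  are not reported in vivo; the truncated exponential is the minimal
  assumption and the 5 s floor avoids degenerate scoring windows.
- **Twitches**: homogeneous Poisson at 0.272 s⁻¹ within active sleep,
  greedily thinned to a 300 ms per-muscle refractory. The dead-time renewal
  expectation `T/(refractory + 1/rate)` gives ≈ 302 events per 30 min
  session, the observed youngest-age mean (302 ± 31).
- **Wake movements**: Poisson onsets at 0.12 s⁻¹ within wake with ≥ 1.9 s
  separation, so each onset opens its own movement bout (~60–70 triggers
  per 30 min, the observed scale).
- **Spikes**: inhomogeneous Poisson via Lewis–Shedler thinning against an
  analytic rate bound (baseline + R_max × the maximum number of kernels
  that can overlap given the event refractory) — exact, and checkable
  against the integrated rate. Kernels invert the fitted response models;
  default unit parameters sit at the published median fit values
  (e.g. twitch responders BL 2.12 sps, R_max 3.86 sps, t_max 0.194 s,
  HWHH 0.186 s).
- **EMG**: modeled as its rectified envelope times a random sign — baseline
  1 (a.u.) during atonia, 3× tonic elevation during wake, twitch bursts
  ~75 ms at 5× baseline, movement bursts 400 ms at 6× wake tone, plus
  folded-normal envelope noise (σ = 0.08 × baseline). Detection operates on
  envelopes, so raw-waveform realism (motor-unit structure, spectral
  content) is deliberately not modeled; passing detection tests therefore
  validates thresholds and timing logic, not robustness to real EMG
  artifacts.
- **Laminar LFP**: a delta dipole (sink at 800 µm, source 300 µm deeper) is
  imposed as the discrete CSD profile and the potential recovered by
  inverting the padded second-difference operator, so the downstream CSD
  reproduces the dipole exactly in the noiseless case; each event drives a
  Gaussian time course (σ = 30 ms, peak 50 ms post-event).
- **Coupled pairs**: train B receives jittered (≤ 1 ms), lagged copies of
  train A's spikes with a retention probability, on top of independent
  stimulus locking — ground truth for shift-predictor validation.

Identical seeds yield bit-identical bundles; all generators accept either a
seed or a shared `numpy` Generator.

What the synthetic sessions do **not** emulate: real sleep–wake bout
statistics (unreported in vivo), per-age parameter drift within a session,
spike-sorting artifacts, movement artifacts in EMG or LFP, and non-Poisson
spiking (bursting, refractoriness within units). Results on synthetic data
bound the pipeline's correctness, not the difficulty of real recordings.

## Problem sizes

The test suite and acceptance script run at desk scale on one CPU:
30 min sessions for scoring accuracy (20 seeds), 200 simulated units with
200 events each for parameter recovery, 100 units for each null calibration
(classification false positives, trial-reliability mean, shift-predictor
coverage), 20 noisy instances per model for the grid-oracle comparison, and
100-event dipole simulations for CSD. These sizes keep the full suite to a
few minutes while leaving Monte-Carlo margins well inside the asserted
bounds.

## Known limitations

- Inhibitory (negative-going) responses are not modeled; the amplitude
  bounds are deliberately nonnegative.
- The deposit adapter reads a generic per-animal timecode-CSV layout; it is
  isolated behind one function so only that function changes when a real
  deposit's schema is inspected.
- The shift predictor's per-reference-event normalization makes the 2-event
  predictor equal the noncongruent-pairing histogram (not half of it);
  this is required for exact cancellation of stimulus locking and is the
  scale on which the confidence bands are computed.
- State scoring assumes bimodal muscle tone; recordings without clear
  atonia/tone alternation are flagged unscorable rather than scored.
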