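# Methods

## Model

Each cortical area is a mean-field attractor network of 150 non-spiking
units: 100 excitatory units on a 10×10 grid, 25 fast feed-forward (FF)
and 25 slow feedback (FB) inhibitory units on coarser 5×5 grids sharing
the same footprint. The state variable of unit *i* is its mean membrane
potential, governed by the delay ODE

    du_i/dt = -u_i/tau_i + sum_j w_ij g_j(u_j(t - delta_ij)) + I_i(t) + xi(t)

with the Freeman gain g(u) = C·Q·(1 - exp(-e^u/Q)). Connectivity:
distance-decaying excitatory coupling between all excitatory units
(decay length 2 grid units), local E↔I coupling within a radius of 3,
no I→I connections, no self-connections, afferent input only onto the
excitatory layer. Inter-area pathways are excitatory and terminate on
the excitatory or the FF-inhibitory layer, never on the FB layer.
Weights carry 10 % multiplicative lognormal-like jitter (seeded), which
is the only randomness in construction.

Integration is explicit Euler–Maruyama at fixed dt = 0.1 ms. Delays are
held as integer step counts; a ring buffer stores past *gain* values
(the delays in the coupling term apply inside g). Noise is additive
Gaussian white, per unit independent, amplitude `noise_sd`·√dt per
step. The choice of a fixed-step explicit scheme is deliberate: delays
plus additive noise make interpolating schemes awkward, and fixed
steps give bit-reproducibility; the E–I pair test integrates the same
system at a 10× finer step and checks that the dynamical classification
(damped vs sustained oscillation) is unchanged.

### Plasticity

Excitatory-to-excitatory synapses follow the saturating Hebbian rule
Δw = η·g_i(t)·g_j(t-δ)·(w_max - w). The discrete increment is capped so
a single update cannot overshoot the w_max fixed point; weights
therefore stay in [0, w_max] exactly, which a property test fuzzes.
Consolidation runs every 1 ms of simulated time by default (5 ms inside
the protocol), with the learning rate scaled by the elapsed interval
(η is per ms), making accumulated weight change robust to the cadence.
Plasticity is restricted to E→E connections: learning in this model
serves assembly formation among pyramidal populations, and plastic E→I
weights would detune the interneuron operating points that set each
area's oscillation bands.

### Parameters and operating points

All network parameters are explicit dataclass defaults. The two
parameter sets were calibrated once so the circuit sits in the
operating regime the model is meant to study, and then frozen:

| parameter | theta areas (ACC, BA9) | gamma areas (BA10, BA46) |
|---|---|---|
| tau_exc / tau_ff / tau_fb (ms) | 10 / 5 / 100 | 10 / 5 / 100 |
| gain Q (all layers) | 5 | 5 |
| w_ee (scale) | 0.008 | 0.008 |
| w_ei_ff / w_ie_ff | 0 / 0 | 0.018 / 0.15 |
| w_ei_fb / w_ie_fb | 1.5e-4 / 0.07 | 1.5e-4 / 0.07 |
| delays ee / ei / ie (ms) | 1.0 / 1.5 / 1.5 | 1.0 / 1.5 / 1.5 |
| tonic drive | 0.7 | 1.0 (BA10: 0.55) |
| noise_sd | 0.03 | 0.0225 |
| w_max / eta | 0.02 / 0 | 0.02 / 1e-6 |

Two mechanisms follow from the time-constant structure. The slow FB
integrator multiplies its input by tau_fb, so its input weight must be
tiny (1.5e-4) to keep it in the sensitive range of the gain; the
resulting E–FB relaxation oscillation paces theta (measured baseline
peak 5.5–7 Hz across seeds). The delayed E–FF loop has a linear
resonance near 45 Hz (total loop delay 3 ms plus membrane lags) and
crosses into a sustained gamma limit cycle once an assembly's total
excitatory drive exceeds ≈1.5 potential units/ms; a drive sweep shows a
working window of roughly 1.6–2.4 with overdrive saturation beyond.
Cell assemblies are vertical three-column strips of the excitatory
grid, so each assembly owns a local E–FF loop and competes with its
neighbours through shared inhibition. The built connectivity already
encodes the assemblies; `train_assemblies` optionally deepens the
stored patterns (per-assembly stimulation with Hebbian consolidation),
but the default protocol does not call it, because substantially
strengthened within-assembly coupling shifts the operating point out
of the calibrated oscillation regimes.

## Protocol

One run is a sequence of fixed 2.5 s epochs ("iterations"); the first
20 % of each epoch is discarded before any metric is computed
(approximate stationarity for the embedding-based estimators; the
remaining 2000 samples satisfy their length preconditions).

- **Gating (Step I).** The ACC epoch is simulated once per run (its
  statistics carry no iteration dependence); its theta-band output,
  normalised to constant envelope, is the endogenous carrier. BA9
  band-limits the external and endogenous streams, Hilbert-extracts
  their envelopes and Pearson-correlates them over a 500 ms window;
  correlation ≥ 0.3 opens the deliberate pathway (ties resolve to
  deliberate), below it the run degenerates to a single feed-forward
  pass. The constant-envelope normalisation is deliberate: the carrier
  conveys phase information, and the raw theta envelope waxes by a
  factor ~3, which would dominate the downstream competition.
- **Goal competition (Step II).** BA10's assemblies each receive the
  carrier plus a tonic salience drive (all start at 0.7). After the
  epoch, each assembly's theta–gamma coupling to the carrier (mean
  vector length, expectancy-weighted) decides the re-weighting: the
  best-coupled assembly's salience is multiplied by 1.125, the others
  by 0.85, clipped to [0.15, 1.9]. Couplings below a noise floor
  (mvl < 0.12) carry no information and the exogenous expectancy
  ranking decides instead.
- **Action competition (Step III).** BA46 receives the carrier, the
  per-assembly expectancy-weighted drive contacting both the excitatory
  and FF-inhibitory layers (FF share 0.08 of the mean excitatory
  drive), and a replay of BA10's assembly signals band-limited to
  9–28 Hz — the alpha/beta window between the carrier and the gamma
  resonance. The replay amplitude shrinks from 0.15 to 0.04 as the
  competition resolves (diffuse while goals are open, focused once
  decided). Effective FF-inhibitory weights grow by 6 % per iteration
  (stabilisation by inhibition). Hebbian learning is on throughout.
- **Readiness potential (Step IV readout).** The pre-SMA is a passive
  accumulator. Its drive is the rectified oscillatory output of the
  tracked BA10 assembly plus the BA9 pathway, scaled by a projection
  strength that itself consolidates between epochs under the same
  saturating rule (initial 0.3, ceiling 1.0, rate 0.15 per epoch
  scaled by relative afferent activity) — the build-up therefore
  tracks synaptic strengthening of the pre-SMA afferents, not raw
  activity. The RP is the exponential moving average (τ = 600 ms) of
  this drive referenced to the first epoch's baseline, sign-flipped to
  the negative-going EEG convention; the reported trend statistic is
  the Spearman correlation of |RP| with time, and a threshold crossing
  (default 1.0) flags the putative transition to awareness. Nothing
  beyond that scalar crossing is claimed about consciousness.

The protocol is staged rather than fully coupled: within an epoch the
areas are simulated sequentially, each driven by stimuli constructed
from the others' recorded output, and the ACC↔LPFC feedback closes
*across* epochs through the salience/expectancy re-weighting. A fully
coupled integrator (`simulate_brain`) exists and is used for the
architecture-level boundedness tests; the staged path is what keeps a
ten-seed, twelve-iteration study inside minutes of CPU time.

## Analysis battery

- **Embedding.** Delay embedding with lag at the first local minimum of
  the average mutual information (equiprobable-bin histogram estimator;
  equal-width bins ripple badly on strongly non-uniform amplitude
  distributions) and dimension from the Kennel false-nearest-neighbour
  test (thresholds 15/2, target fraction < 1 %, floor m = 2). Exactly
  periodic noise-free signals revisit orbit points exactly and
  degenerate both automatic criteria; such signals should be embedded
  with explicit parameters.
- **Correlation dimension.** Grassberger–Procaccia pair counting with a
  Theiler window of lag·m, ~50 log-spaced radii over three decades,
  trajectory subsampling above 4000 points, and an automatic scaling
  region: the longest contiguous run of radii (≥ 6) whose
  central-difference local slopes vary by < 10 % of their mean, with
  pair-count ≥ 30, C(r) ≤ 0.5, and r below 0.35× the attractor
  diameter. The last restriction matters: macroscopic radii reflect the
  attractor's gross shape (for theta-dominated mixtures, the slope-2
  orbit shell) rather than its dimension, and admitting them made
  early-protocol estimates bimodal. The restriction is anchored on the
  oracles (noiseless sine 1.01; Lorenz 1.96 against the textbook 2.05
  and an in-test brute-force pair count). Estimates without an
  admissible flat region at fit R² ≥ 0.98 are flagged unreliable, as
  are estimates whose automatic embedding never met the FNN criterion
  (white noise).
- **Largest Lyapunov exponent.** Rosenstein nearest-neighbour
  divergence with mean-period exclusion (capped at a tenth of the
  series), 1500 reference points, and a fit over the initial linear
  segment (up to 80 % of the rise toward saturation); immediate
  saturation or fit R² < 0.9 flags the value. Validated against a
  Benettin two-trajectory renormalisation of the Lorenz system inside
  the test suite (0.95 vs 0.9 ± 0.15 per model time).
- **Sample entropy.** SampEn(m = 2, r = 0.2·SD, Chebyshev), strided to
  3000 points, with a capped sentinel (12) and flag when no template
  matches exist.
- **Spectral.** Hann STFT; band summaries over theta 4–8, alpha 8–13,
  beta 13–30, gamma 30–80 Hz; Welch dominant frequency.
- **PAC.** Zero-phase FIR band-passes (three cycles of the low edge,
  capped at a quarter of the window so short epochs remain filterable),
  Hilbert phase/amplitude, mean vector length |⟨A·e^{iφ}⟩|/⟨A⟩, and a
  circular time-shift surrogate null (≥ 200 shifts of at least one slow
  cycle; p = (1+#{null ≥ obs})/(1+n)). The null is checked for
  uniformity in the suite. Note that the time-shift null is void for
  *strictly periodic* modulation (a shift preserves the coupling);
  the benchmark generator therefore gives its carrier a phase random
  walk, as real carriers drift.

## Synthetic benchmark generators

The fixture module generates sines, white and AR(1) noise, Lorenz and
Rössler flows (adaptive RK45 at tight tolerance, transient discarded),
and theta-modulated gamma with either cosine or von-Mises ("burst")
envelopes. These are oracles for the estimators, not models of EEG:
they lack 1/f background, nonstationarity, artifacts and volume
conduction, so a passing battery certifies the estimators' behaviour
on signals of known structure, not performance on clinical data.

## What the default study reproduces, and what it does not

Ten seeds of the default protocol (the same batch the acceptance
script re-runs) give, for the tracked BA46 assembly:

- First-iteration correlation dimension: seed-median ≈ 3.8 — the
  high-dimensional deliberation state.
- Monotone D2 decline across iterations (Spearman ρ < 0, p < 0.05) in
  9/10 seeds.
- Dominant-frequency migration: BA10/BA46 below 30 Hz in iterations
  1–2 and in gamma (≈ 44–46 Hz) in iterations 10–12 in 7/10 seeds
  (three distinct weight-jitter phenotypes miss it: one early
  gamma flicker in a single epoch, one BA46 fast loop too weak to
  ignite, one BA10 that arrives theta-entrained at the ignition
  drive and stays locked — a regime-switching hysteresis).
- RP: |RP| vs time Spearman ρ ≈ 0.94–0.98 in all seeds; flat, with no
  threshold crossing, when all stimuli are zero.

Known limitations, stated plainly:

- **The final-state D2 reads ≈ 2.4–2.6, not 1.8.** The stabilised
  attractor is a theta-entrained gamma oscillation — geometrically a
  noisy 2-torus — and a pair-counting estimator cannot read such an
  object below 2 unless it mode-locks to a closed curve, which the
  calibrated network does not robustly do. Configurations whose final
  state is a bare gamma limit cycle measure ≈ 1.1 instead, and the
  region-selection settings that would sometimes read the torus lower
  are exactly those that destabilise the early-iteration estimates.
  The package reports the number its estimator computes.
- **λ₁ and sample entropy trend upward, not downward.** Both estimators
  are timescale-sensitive: per-second divergence and fixed-tolerance
  template matching both read *faster* signals as larger, and the
  protocol's dominant timescale accelerates sevenfold (theta → gamma)
  while the attractor becomes more ordered. D2, which is invariant to
  time rescaling, carries the stabilisation trend; λ₁ and SampEn
  confound it with the frequency shift. A per-cycle renormalisation
  would change their units away from the battery's oracle-anchored
  definitions, so the confound is documented rather than hidden.
- Two of ten weight-jitter seeds produce a weak BA46 fast loop (one
  never ignites gamma under the default drive ceiling); they account
  for the counts above.
- The ACC and BA9 epochs are stationary per run and reused across
  iterations; emotional/subcortical structures enter only as the
  exogenous expectancy weights; nothing downstream of the early RP
  (decision execution, motor output) is modelled.
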