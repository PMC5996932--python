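# Methods

This note documents the model implemented by `placenergy`, the choices made
where the design was genuinely open, and what the synthetic test conditions
do and do not show.

## Single-neuron energetics (`hh_energy`)

The membrane follows the classical squid-axon conductance model with
parameters `C_m = 1 µF/cm²`, `g_Na = 120`, `g_K = 36`, `g_l = 0.3 mS/cm²`,
`E_Na = 50`, `E_K = −80`, `E_l = −56 mV` and resting potential
`V_r = −67.3 mV`. The gating rates are functions of the depolarization
`u = V_m − V_r` in the standard orientation (depolarization opens the m and
n gates and closes h); the two removable 0/0 singularities of the α_n and
α_m expressions, at `u = 10` and `u = 25 mV`, are filled with their analytic
limits (0.1 and 1.0 ms⁻¹). The initial condition is the resting fixed point
`x_∞(V_r) = α_x/(α_x+β_x)`.

Integration is fixed-step RK4. `dt = 0.01 ms` is the default; halving it
changes the per-spike energy by less than 10⁻⁵ relative, so the solver error
is far below every tolerance used in the analyses. The stimulus is a single
rectangular pulse, 10 µA/cm² for 1 ms — the minimal protocol that elicits
exactly one action potential; amplitude, window and duration are all
configurable.

Each conductance dissipates Joule heat `g·gates·(E−V)² ≥ 0`; the electrode
contributes signed work `V·I`. Total power is the exact sum of the four
terms, and the per-spike energy is its trapezoidal integral from stimulus
onset to full repolarization, defined as the first post-peak sample with
`|V−V_r| ≤ 2 mV` and the slow n gate within 0.02 of rest. Because the window
is anchored to repolarization rather than to the end of the simulation,
extending the simulated interval does not change the result.

The integral is a power *density*; an effective membrane area converts it to
absolute energy. A calibration run of the default protocol gives
187.87 nJ/cm², so the shipped calibration is simply 1 cm², reproducing the
~188 nJ per-spike constant. The area is a bookkeeping constant, not an
anatomical surface; the network takes its per-spike energy scale `C` as an
independent parameter (default 188 nJ), so network behaviour never depends
on the calibration.

## Arena, exploration, sensing (`environment`)

The arena is a cube of side `L = 20` length units. Exploration is a 10,000
step random walk with fixed step length 1: each direction is uniform on the
unit sphere and redrawn whenever the step would exit the cube. Redraw (vs.
specular reflection) was chosen to keep every step length exact; it mildly
biases near-wall headings inward, which is indistinguishable from reflection
at the population level. The start position is uniform over the cube.

Sensing returns the distances to the Left/Front/Down walls scaled by
`1 + α·η` with `η ~ U(−1,1)` and `α = 0.1`. η is drawn independently per
coordinate and per step (a shared-η variant would correlate the three
coordinate errors; independence is the more general choice). Readings are
clipped to `[0, L]` so the normalized network input stays inside the unit
cube; without clipping, near-wall readings could leave the arena by up to
`α·L`.

## The place-cell network (`place_network`)

Weights are initialized entry-wise as
`w = (1 + exp((γ−½)/(2σ_w²)))⁻¹`, `γ ~ U(0,1)`, with `σ_w = 0.1`. The map is
centrally symmetric about 0.5 and, at this width, strongly bimodal toward 0
and 1 — initial preferred positions concentrate near walls and corners,
which is what lets learned fields tile the boundary of the arena rather
than collapsing to its center. `σ_w` is deliberately a separate parameter
from the tuning widths `σ_j`.

Firing power is Gaussian in normalized input space,
`P_j = C_j R_m exp(−u_j²/(2σ_j²))` with `u_j = (1/n)‖X′/L − W_j‖`, `n = 3`
sensory inputs, so `0 ≤ P_j ≤ C_j R_m` (≈3.8×10³ nW at the default means).
The response threshold is per cell, `P_thr,j = 0.3·C_j R_m`; since the `C_j`
differ by only ~5%, this is nearly a global threshold (a shared-threshold
mode is available via `net.global_threshold`).

Learning is a forward-Euler step of the batch competitive rule: every
responding cell moves `W_j ← W_j + μ(X′/L − W_j)`, `μ = 0.001`, which
contracts the distance to the input by exactly `(1−μ)` — the identity the
tests assert. If no cell crosses threshold the single most active cell
learns (winner-take-all fallback), so learning never stalls; the same
fallback keeps decoding defined everywhere. Weights remain in `[0,1]` for
any update sequence because each update is a convex combination. Winner
ties break to the lowest cell index, and `C_j`, `σ_j` draws are redrawn if
non-positive (a ~10⁻⁸ event at the default means) to keep the contracts
total.

Field centers, field sizes and energy budgets are computed in a **frozen**
second pass over the same readings: the power log of the learning pass
mixes early, unlearned responses into the field statistics, whereas the
frozen pass describes the converged code (an `online` option reproduces the
in-pass accumulation). The center is the power-weighted centroid over *all*
steps of the pass; the place field is the set of supra-threshold steps; the
energy is `Σ_t P_j(t)·Δt` with `Δt = 1 s` of dwell per step, the convention
under which powers in nW give per-cell totals on the 10⁶ nJ scale. A cell
with zero summed power reports an empty field with an undefined (NaN)
center rather than an error.

Decoding is the population vector over the responding set,
`Loc = Σ_J P_j C_j / Σ_J P_j`, which lies in the convex hull of the
responding centers and therefore inside the arena. Locating error is
`‖Loc − X‖/L` against the *true* position; centers and decoding use the
noisy readings, because those are all the network ever sees.

## Analyses (`analysis`)

* Locating-error series with mean/max summaries and an OLS slope test over
  the trailing 5,000 steps as a divergence diagnostic.
* Field statistics (per-cell peak power and field size) with
  Freedman–Diaconis histogram binning.
* Center collinearity: the three pairwise coordinate correlations and the
  leading-eigenvalue fraction of the center covariance (1/3 for an isotropic
  cloud, 1 for a line).
* Energy normality: the Lilliefors variant of the Kolmogorov–Smirnov test
  (mean and variance estimated from the sample) at α = 0.01. Lilliefors was
  chosen because the null parameters are unknown; the statistic is reported
  so another omnibus test can be swapped in.
* Field-size sweep: the full pipeline re-run over a grid of `σ` means with
  paired seeds per grid point, recording mean error, mean field size and
  mean energy. The "large-field" regime used in the contrast analyses is
  `σ_mean` scaled ×6 to 0.18 with `σ_sd` kept at 0.005; scaling only the
  mean preserves the relative homogeneity that makes large-field energy
  budgets approximately normal.

## Sizes and reproducibility

One global seed derives three independent stage streams (walk, sensory
noise, network initialization) by `SeedSequence` spawning in that fixed
order, so a saved config plus seed reproduces every artifact byte for byte,
and stages can be re-run in isolation. The test suite runs the reference
configuration (200 cells, 10,000 steps) for ten seeds and the σ sweep at a
reduced size (100 cells, 5,000 steps, 3 paired seeds per grid point, five
replicate sweeps), which is the smallest design that keeps the stochastic
contrasts (interior error minimum, normality flip, collinearity increase)
stable across seeds while the whole suite stays in the low minutes.

## What the synthetic conditions do not show

The generator *is* the model's world: a featureless cube sensed through
three exact-but-noisy wall distances. Passing tests therefore say nothing
about cue conflict, landmark identity, vestibular/path-integration input,
multiple or remapping environments, or anisotropic 3D coding in real
animals. Firing is a deterministic power value — no spike trains, no
trial-to-trial variability — and synaptic-transmission energy is outside
the model: the per-spike constant covers ion-channel dissipation only.

## Known limitations

* Peak learned firing powers sit near the analytic cap `C_j·R_m`
  (≈3.7–4.2×10³ nW across seeds): with 10⁴ visited locations the nearest
  visit to a learned center is typically ~0.5 arena units, so the Gaussian
  tuning is sampled close to its peak. Reports quoting lower typical maxima
  imply sparser effective sampling than the stated trajectory density
  provides.
* The locating error (~0.19 of the arena side at the defaults) mixes model
  systematic error (a finite set of centers decoding a continuum, and three
  inputs compressed through scalar powers) with sensory noise; the two are
  not separated here.
* The random-walk redraw rule, the clipping of readings, and the 1 s dwell
  per step are conventions; alternatives (reflection, unclipped readings,
  other dwell times) rescale energies but leave the qualitative contrasts
  intact.
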