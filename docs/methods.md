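# Methods

This note documents the models and procedures implemented in `headcode`,
the defaults they ship with, and the choices made where a convention had to
be fixed.

## Scientific setting

Head direction (HD, the wrapped angle θ ∈ [0, 2π)) and angular head
velocity (AHV = dθ/dt, counterclockwise positive) are interdependent
variables: the current heading is the running integral of the velocity.
The package studies how a neural population can encode both at once, at
three levels: a firing-rate RNN trained to integrate AHV into HD; per-unit
tuning statistics that separate single-peaked (SP) from multipeaked (MP)
units; and population-level analyses (feedforward decoding, manifold
geometry) that link tuning shape to what each subpopulation encodes well.

## Ring-integrator RNN

**Dynamics.** N fully recurrent units follow a rate model in which firing
tracks synaptic input instantaneously while the input relaxes slowly:

    r_i(t) = max(0, tanh(s_i(t)))
    τ ds_i/dt = −s_i + Σ_j W_rec[j,i] r_j + Σ_k W_in[k,i] I_k + b_i

integrated by Euler steps of dt = 25 ms with τ = 250 ms (relaxation factor
dt/τ = 0.1). Rates are bounded in [0, 1); units with s ≤ 0 are silent.

**Task.** Three inputs: (cos θ₀, sin θ₀, AHV_t). For the first 10 steps of
a trial the heading inputs are active and AHV is zero; afterwards the
heading inputs are zero and the scalar AHV input follows the AR(1) process
AHV_t = σX_t + m·AHV_{t−1} with σ = 0.03 rad/step, m = 0.8, X_t ~ N(0,1) —
stationary SD 0.05 rad/step, i.e. 2 rad/s at the 25 ms grid, a realistic
rodent turning distribution. Two linear readouts are trained toward
(cos θ_t, sin θ_t) where θ_t is the exact integral of the velocity input.
Half of the trials contain a contiguous zero-AHV segment of up to one third
of the trial, which forces the solution to hold heading without input (the
attractor property).

**Loss and training.** Mean-squared output error plus an L2 penalty on the
mean squared firing rates of recurrent and output units. The penalty
weight `rate_l2` defaults to 1e−3: strong enough that a minority of units
adopts low-rate, multipeaked profiles, weak enough not to impair
integration. Optimization is backpropagation through time with minibatch
Adam, global gradient-norm clipping at 1.0 (long-horizon BPTT diverges
without it), and a step learning-rate decay (×0.2 at 60% and 85% of
epochs) that stabilizes late training. Weight init: recurrent gain
1.1/√N Gaussian; input 1/√3; readout 1/√N; zero biases. Training aborts
with diagnostics if held-out error rises for 10 consecutive epochs.

The reference formulation trains the same loss with a Hessian-free
second-order optimizer; a first-order optimizer reaches the same qualitative
solution (stable integration, SP/MP dichotomy) but epoch-for-epoch error
traces are not comparable, and all trained-network quantities in this
package should be read as stochastic reproductions, not numeric replicas.

**Scaled study conditions.** The package's study-scale configuration is
100 units, 500-step trials, 250 training trials, 500 epochs with
`rate_l2 = 1e-2` — the setting at which training reliably converges
(held-out total NMSE ≈ 2%) and the emergent SP/MP structure is sharpest
(a minority of low-MVL multipeaked units whose per-peak FWHM is narrower
than the single-peaked average). Sessions for analysis concatenate
independent trials (each with fresh θ₀ and velocity stream) into one long
series with seams recorded; 50,000–60,000 steps (~21–25 min equivalent) is
the default analysis length.

With a first-order optimizer the velocity input stays more distributed
across units than the concentrated solution the second-order-trained
reference reports: the low-MVL class is smaller (~4–9% of units) and,
while it carries the most velocity information per unit, it does not beat
the ~10×-larger SP population at absolute AHV decoding, and trajectory-
length changes under SP→MP replacement do not track AHV-decoding changes
positively. The corresponding acceptance tests assert the reference
directions and are expected to fail at this scale; the synthetic-data
path (where the MP class demonstrably carries the velocity gain) confirms
the analysis pipeline itself reproduces the dissociation when the code
has it.

**Deactivation.** Unit knock-outs are simulated by clamping the selected
hidden states to zero after every Euler step; performance is the total
normalized error, Σ_l 100·Σ(y_l−y*_l)²/Σ(y*_l−mean y*_l)² over the two
outputs, so a mean predictor scores exactly 200.

## Preprocessing (biological path)

Tracked angles are circularly unwrapped to an accumulated angle, linearly
resampled onto a 25 ms grid, and smoothed with a Gaussian kernel
(σ = 200 ms, truncated at 3σ per side, renormalized to unit sum). AHV is
the accumulated angle convolved with a derivative-of-Gaussian kernel
G·(x−μ)/σ², normalized so a unit ramp returns exactly its slope. Spike
trains are binned at 25 ms and convolved with the same unit-sum Gaussian,
so each spike contributes unit mass (divided by the bin width for Hz).

Edge policy: the source convention is not fixed by the formulas, so samples
within 3σ of a segment edge carry a validity-mask bit and are excluded from
tuning statistics rather than padded or reflected. Tracking dropouts are
bridged by interpolation up to a configurable `max_gap` (default 1 s);
longer gaps raise, since splicing across them would fabricate velocity.

## Single-unit statistics

All statistics operate on 50 equal HD bins over [0, 2π) (AHV curves use
0.2 rad/s bins), with per-bin SDs from 50 half-sample permutations.
Units with mean rate below 1e−4 are excluded before analysis.

* **MI_HD** (bits/s): Σ_i p(i)·fr(i)·log₂(fr(i)/fr) over occupied bins,
  with fr the occupancy-weighted mean rate; bits/spike = bits/s ÷ fr.
  Zero-rate bins contribute nothing; a silent unit scores 0.
* **Pr_AHV**: within each rotation-sign subset (AHV > 0 and AHV < 0,
  each requiring ≥ 100 samples), the absolute partial Pearson correlation
  between rate and AHV controlling for HD,
  (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)); the larger of the two absolute
  values is reported. The conditioning variable is the raw wrapped angle
  (the formula's literal reading); a cos/sin-regression variant is
  available behind `conditioning="cos_sin"` for sensitivity analyses.
  All three variables are restricted to the sign subset.
* **Significance**: the rate series is circularly shifted by a random
  interval of at least 30 s (end wrapped to beginning), 1000 times by
  default; a unit is significant if the observed statistic exceeds the
  99th percentile of the shuffled distribution. On AHV-independent
  synthetic units this flags ~1% or fewer, as a 99th-percentile criterion
  should.
* **MVL** (Rayleigh r): |Σ λ_i e^{jθ_i}| / Σ λ_i over occupied bin
  centers — 1 for one concentrated peak, ≈0 for uniform or symmetric
  multipeak curves. For a von Mises curve with concentration κ it equals
  I₁(κ)/I₀(κ), which the tests use as an oracle.
* **SP/MP classification** (two-rule test, strictness α, default 0.10): a
  unit is SP iff (i) no bin outside the contiguous circular half-peak
  range around the global maximum exceeds half the maximum, and (ii) fewer
  than α·50 bins outside the 20%-peak range exceed 20% of the maximum.
  The "ranges" are defined as the contiguous circular runs of bins above
  the respective level around the global peak — the definition that makes
  both rules well posed on a circle. The classifier is monotone in α.
  For RNN populations an MVL threshold of 0.5 (`classifier="mvl"`) stands
  in for the visual-inspection split, justified by the bimodal MVL
  distribution of trained networks.
* **FWHM**: curves are min-subtracted first. SP: angular span between the
  two half-maximum crossings around the global peak, linearly interpolated
  between bins. MP: local maxima are found circularly (the curve is tiled
  so wrap-point peaks are not split) with a minimum separation of 10 bins
  (8 for recorded neurons); a peak qualifies if at least one flank drops
  below half its height, its width being the full span or twice the
  detectable half-span; the unit's FWHM is the mean over qualified peaks,
  measuring local sharpness rather than total angular spread.
* **MI–Pr relationship**: a continuous two-segment least-squares fit of
  Pr_AHV on MI_HD (breakpoint by grid search over interior quantiles; basis
  [1, (x−c)⁻, (x−c)⁺]), with R² compared against single-line, quadratic
  and exponential (a·e^{bx}+c) alternatives.

## Decoding

A multilayer perceptron (hidden layers 64-128-64, ReLU, Adam, L2 weight
decay 5e−2 for HD and 5e−3 for AHV — scikit-learn `MLPRegressor`) maps
instantaneous population rates to the target under 5-fold cross-validation.
The HD network regresses (cos θ, sin θ) and the angle is reconstructed by
atan2 and wrapped modulo 2π, avoiding the wrap discontinuity; skill is the
Pearson r between cosine-transformed predicted and actual angles (raw
values for AHV). Folds are contiguous temporal blocks by default, limiting
leakage through autocorrelation (random folds are available). Inputs are
standardized per unit on the training fold only. Epochs, learning rate and
batch size are not dictated by the source description; defaults
(max_iter 120 with early stopping, lr 1e−3, batch 256) are recorded in
`DecoderSpec`, and `max_samples` evenly subsamples long sessions for
bounded runtimes. On pure-noise inputs the decoder's mean r over 20 seeds
is within ±0.05 of zero.

## Geometry

* **Effective dimensionality**: ED = (Σλ)²/Σλ² over covariance
  eigenvalues — the participation ratio, in [1, d], rotation invariant.
  Computed on the full z-scored activity time series of a subpopulation
  (the binned-state variant is also exposed on the `Manifold` object).
* **Manifold**: each unit z-scored over the whole session, averaged within
  360 HD bins; unoccupied bins are filled by periodic interpolation and
  recorded. Trajectory length is the cumulative Euclidean distance between
  adjacent bin states; the ring is left open by default (`close_ring`
  adds the final chord — the two differ by one part in 360).
* **FWHM-ordered subpopulations**: SP units sorted by FWHM (ties broken by
  unit id) and cut into `n_groups` contiguous groups of `group_size`;
  when the count does not divide evenly the groups are near-equal instead,
  and oversupply drops the broadest units.
* **Replacement experiment**: for each SP group and fraction in
  {0.2, …, 0.8}, random MP substitutions (without replacement within the
  MP pool, 20 replicates by default) are compared to the pure-SP baseline
  in trajectory length and decoding r for both targets.

## Synthetic populations

The generator exists so every downstream stage has ground truth: SP units
are von Mises bumps, rate = base_rate·exp(κ(cos(θ−μ)−1)), with κ drawn
log-uniformly from (1, 8) — FWHM roughly 0.9–2.6 rad, matching the spread
of tuning widths over which the geometry analyses operate. MP units are
sums of 2–4 bumps of fixed FWHM (default 0.5 rad) whose centers are drawn
without replacement on a coarse grid guaranteeing ≥ 2× width separation.
An optional linear-rectified AHV gain, rate × max(0, 1 + g·|AHV|), is
applied symmetrically or only for a per-unit preferred rotation sign
(default), and is assigned to the MP class by default — emulating the
association between multipeaked tuning and velocity sensitivity that the
trained RNN develops, with g ∈ (0.15, 0.35) s/rad chosen so that Pr_AHV of
gained units clears the shuffle threshold on ~20 min sessions without
dominating the HD tuning. Noise is Poisson spike counts per 25 ms bin
(biological path) or additive Gaussian rate noise (RNN-like path).

What the generator does **not** emulate: spike-sorting errors, slow
nonstationarities (electrode drift, behavioral state changes), theta
rhythmicity, anticipatory time intervals of HD cells, or correlated noise
across units. Passing recovery tests therefore certifies the statistics
pipeline, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

* Tuning statistics exclude unoccupied bins (occupancy renormalized);
  MI of a silent unit is 0 by definition; MVL of an all-zero curve is NaN.
* Pr_AHV subsets with degenerate variance are skipped; if both rotation
  signs are degenerate the statistic is NaN and the unit is excluded from
  population fits.
* Near-silent units (active in <1% of bins) can have formally defined but
  meaningless statistics; the mean-rate exclusion plus significance
  testing keeps them out of SP/MP populations.
* The AR(1) generator rejects momentum ≥ 1 (nonstationary); the Euler
  integrator requires dt ≤ τ.
* Session containers round-trip bit-identically through the .npz + JSON
  sidecar format; all randomness is seeded and recorded.

## Known limitations

* Trained-network quantities vary across seeds at the package's scale;
  comparisons (SP vs MP decoding, FWHM ordering) are robust, individual
  r values move by a few hundredths.
* The two-rule classifier and the MVL-threshold split agree on clean
  curves but can disagree on broad-and-shallow multipeak units; both
  labels are available.
* The piecewise MI–Pr fit's breakpoint is only weakly identified when one
  class is small, as it is at 64 units.
* The biological reader ingests plain-text layouts; binary acquisition
  formats must be exported to text first.
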