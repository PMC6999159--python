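# Methods

This note documents the model as implemented, the reasoning behind every
tunable constant, what the synthetic data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Model

### Units, time, and input coding

All timing is relative: input rate vectors are L2-normalized to a
magnitude of one spike per time unit, which defines the time unit, and
every time constant below is expressed in those units. Each input channel
is an independent Poisson process with rate proportional to the raw
feature value (no offset); interarrival times are exponential and, by
superposition, the pooled input process is Poisson with rate Σλ_i and
channel probabilities λ_i/Σλ_i. Magnitude carries no class information —
classification is purely angular — which matches intensity-insensitive
data such as digit rasters.

### Neurons

Output neurons are LIF units with v_rest = v_reset = 0, no refractory
period, exponential decay with **τ_mem = 15**, delta synapses, and an
inclusive static threshold (v ≥ v_th fires). τ_mem controls an accuracy /
compute trade-off visible in the closed-form moments: the steady-state
mean is τ_mem(w·λ) while the squared coefficient of variation scales as
1/τ_mem, so a slower membrane discriminates finer angular differences at
the cost of integrating more spikes. v_th must sit just below the
steady-state mean of a perfectly matched neuron (= τ_mem for unit-norm
vectors); the sweep grid 13.5–14.25 spans the useful range, and smaller
networks want the lower end. Defaults: **v_th = 13.5**.

The dopaminergic unit inverts the LIF design: v_rest = 2 **above**
v_th = 1, so its potential relaxes upward and self-fires. Its rise
constant is **τ_d = 200/ln 2 ≈ 288.54**, the unique value for which the
reset-to-threshold time is exactly the 200-unit recognition window. (The
constant is sometimes written as "200 ln 2", which would give a 96-unit
rise; only 200/ln 2 is consistent with a 200-unit rise from reset given
this rest/threshold pair, so that is what we implement and expose in
config.) Output-layer spikes subtract **inhibit_amount = 2.0** from its
potential — one recognition spike postpones the next dopamine fire by
more than a full rise period, so the unit only fires when the layer is
silent for a whole window. The inhibition magnitude is a free parameter
of this implementation (only "strong enough to silence during
recognition" matters); it is configurable.

### Plasticity

Pre-synaptic traces: +1 at each spike on the channel, exponential decay
with **τ_pre = 200** (equal to the recognition window so the trace
integrates most of the presentation). At stationarity E[pre_i] = λ_i
τ_pre, so pre/τ_pre is an unbiased estimate of the rate vector; the unit
increment is forced by that moment identity.

The stabilized one-sided rule Δw = α(pre/τ_pre − w) is applied to the
winning neuron at each of its fires, followed by a per-weight cap and L2
renormalization of the vector. α = **0.01** normally; a dopamine fire
boosts all α to **1.0**, and a neuron's α reverts the next time it fires
(after that one boosted update) or receives lateral inhibition — so only
the first neuron to respond after a dopamine fire actually does a
one-shot adoption. The uncorrected rule Δw = α(pre − offset) is kept
(`stdp_static_offset`) purely as the instability comparison: it drives
weights to the bounds (binarization) instead of the cluster center.

**The weight cap.** Individual weights are clipped to [0, w_cap] *before*
renormalization, on every update; its purpose is to stop stochastic trace
outliers from distorting the normalization during boosted learning. The
cap only functions correctly when it sits above the typical component of
a unit-norm input (≈2.5× for 784-dim rasters: 0.2 vs ~0.08). `RunConfig`
defaults to **w_cap = 0.2** (the raster value); the synthetic study at
dim 64 uses **0.5** via `protocols.synthetic_study_config`, preserving
the same ratio for its 16-channel supports (components ≈ 0.25). If the
cap is set *below* the data components, converged weights pin at the cap,
the post-clip norm falls below one, and renormalization systematically
inflates unused channels — a failure mode we verified and document here
so nobody "simplifies" the scaling away.

Dopaminergic weights: d_j ← d_j(1 − η) when neuron j fires while
unfrozen (η = **0.1**; only relative order matters, since stimulation is
normalized by max d), followed by L2 renormalization of the fan-out —
which *is* the gradual potentiation of everyone else, keeping weights
positive and well-separated in finite precision. Consequently argmax d is
always a least-fired neuron: firing frequency is the proxy for how costly
a neuron is to sacrifice. Depression applies on every unfrozen fire,
including dopamine-stimulated ones, so a just-reassigned neuron is
immediately protected.

Homeostasis (baseline networks only): effective threshold v_th + θ_j with
θ_j += **0.05** per fire and decay constant **1e5**. These constants are
this package's choices for the comparison baseline; they spread activity
on the timescale of a few hundred presentations.

### Event-driven simulation

Neurons can only cross threshold when a spike arrives, so the simulator
jumps between events: draw the next pooled-input arrival (buffered
uniforms converted to exponential + channel via the CDF — a rate change
only rebuilds the CDF, and instrumentation cannot shift the stream);
process the dopaminergic self-fire first if its closed-form crossing time
is earlier (ties break input-first, a measure-zero case); decay all state
lazily across the gap. A dopamine fire adds gain·d_j to every membrane
with gain = κ·v_th/max(d); **κ = 1** makes the targeting deterministic
(the max-d neuron reaches threshold exactly; a relative tolerance of
1e-9 on that comparison absorbs rounding). Among simultaneous crossings
the lowest index wins. Dopamine-stimulated spikes count toward the
recognition quota.

A presentation ends at **5** output spikes. In CFN training rates are
never escalated (the dopamine unit handles non-recognition); at inference,
and in baseline training, rates are multiplied by **1.5** per elapsed
200-unit window, up to **10** steps, after which classification falls
back to accumulated spike counts (or highest membrane potential if there
were none) and the fallback is flagged. Between samples the membrane
potentials, traces, dopamine potential, and boosted learning rates reset;
weights, dopaminergic weights, and homeostatic offsets persist. Freezing
disables every learnable update and the dopamine unit, leaving membrane
dynamics free — evaluation and label assignment run only on frozen
networks, verified by hashing the learnable state around every evaluation
block.

### Protocols

Disjoint curricula present classes strictly sequentially (ascending order
by default, configurable); after each task the network is frozen, each
neuron is assigned the class with the most spikes during an inference
pass over **all training samples of the classes seen so far** (the
alternative — current-task samples only — would bias labels toward recent
classes), silent neurons are excluded rather than defaulted, and accuracy
is measured on the test split of seen classes, winner-take-all by spike
count with lowest-index tie-breaks. No linear readout anywhere — labeling
a neuron is the only supervision, applied post hoc. The hyper-parameter
sweep reports training-split accuracy only (model selection must not see
the test split). The trigger statistic segments training dopamine fires
per task and compares the first and last decile of samples: a declining
curve is the signature of novelty detection.

## The synthetic data generator

The generator stands in for digit rasters so every experiment runs from
code in minutes. It emulates, deliberately:

- **tight angular clusters**: each class is 3 clusters; samples are a
  center plus per-channel Gaussian noise (sd 0.02), clipped at zero and
  renormalized (realized within-cluster dot ≳ 0.98);
- **magnitude insensitivity**: everything is unit-norm;
- **sparse, bounded-intensity supports**: centers occupy 16 of 64
  channels with near-equal components ≈ 0.25 (sparsity 0.75), keeping
  components under the (scaled) weight cap the way ink pixels stay under
  0.2 at dim 784;
- **a shared core**: half of every support (8 channels, with identical
  intensities) is common to the whole dataset, like the central ink mass
  all digits share. This is what makes *trained* neurons angularly closer
  to a novel class (dot ≈ 0.6) than untrained random-weight neurons are
  (≈ 0.33 mean, ≲ 0.6 max), which is precisely the geometry that makes
  naive networks reuse and overwrite their trained neurons. Without the
  core, escalation happily recruits fresh random neurons and no baseline
  collapses — the failure mode being studied would be absent.

Realized geometry is verified after generation (mean within-cluster dot ≥
`intra_dot_min` = 0.95, between-class dot ≤ `inter_dot_max` = 0.65) with
bounded re-draws of the centers. Initial network weights are drawn
uniform on [−w_cap, w_cap] and rectified by the cap-and-normalize step,
giving diverse ~half-sparse receptive fields.

What the generator does **not** emulate: heavy-tailed intensity profiles,
within-class style variation beyond isotropic noise, class imbalance,
correlated (stroke-like) pixel noise, and the 784-dim scale at which
shot-noise fluctuations relative to the threshold gap are several times
smaller. Passing the synthetic study therefore demonstrates that the
*mechanisms* work (novelty detection, isolated one-shot adoption,
least-used targeting, graceful degradation), not that any particular
real-data accuracy will be met. The real-data protocol is nevertheless
fully implemented (IDX reader, escalation, sweep — see
`examples/mnist_disjoint.py`).

**Study sizes.** The reference study uses N = 32 neurons, dim 64, 4
classes × 3 clusters × 60 samples (48 train / 12 test per class), 1 epoch
per task, five seeds, each seed drawing its own dataset, initialization
and presentation order. These sizes keep the full comparison (four
variants plus the interleaved reference, five seeds) at a few minutes of
one CPU while leaving all qualitative contrasts far from their decision
boundaries (e.g. CFN ≈ 97% vs no-dopamine ≈ 35%).

## Numerical choices

- Exponential decay is applied analytically per event gap — no
  integration error anywhere; the only approximation in the package is
  Monte-Carlo sampling.
- Threshold comparisons are inclusive (≥); the dopamine-stimulation
  crossing uses a 1e-9 relative tolerance so the constructed
  "exactly v_th" increment cannot round to a miss.
- Ties: simultaneous crossings → lowest neuron index; label-count ties →
  lowest class index; input-vs-dopamine time ties → input first. All
  continuous quantities make real ties measure-zero.
- The pooled-event sampler buffers uniform draws; exponentials are formed
  as −log1p(−u)/Σλ. Rate escalation reuses buffered uniforms (they are
  rate-independent), so trajectories are bit-reproducible for a given
  seed regardless of capture settings.
- Degenerate inputs fail loudly: all-zero samples ("silent sample"),
  all-clipped weight vectors, label assignment where no neuron ever
  fires, schedules naming absent classes.
- Event capture nudges exactly-simultaneous cascade events (dopamine →
  stimulated output) by one float ulp to keep recorded times strictly
  increasing.

## Known limitations

- Single layer only; no delays, conductances, or refractory dynamics.
- The event loop is pure Python/numpy per event: fine for ~10⁶ events
  (the full study), not for 6,400-neuron full-MNIST runs, which need
  hours.
- The dopaminergic inhibition magnitude and η are behaviorally
  over-determined (only order/strength classes matter), so their exact
  values are conventions, not fits.
- With κ < 1 dopaminergic targeting becomes stochastic; the progress
  guarantee (every CFN training presentation terminates) holds only for
  κ ≥ 1.
- Homeostasis baseline constants are conventions for comparison, not
  tuned optima; its accuracy is sensitive to them.
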