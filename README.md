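# cfnet — controlled forgetting in spiking neural networks

`cfnet` is an event-driven simulator for single-layer spiking neural
networks that learn **unsupervised, online, and forever**: classes can be
presented strictly one after another (never revisited) and the network
still retains what it learned earlier. It implements the *controlled
forgetting* mechanism — a self-firing dopaminergic neuron that detects
novel inputs and steers one-shot re-learning into the least-used neurons —
together with its non-dopaminergic baselines, the analytic
membrane-potential statistics used to set firing thresholds, and the full
training/evaluation protocol. It is aimed at researchers studying
continual learning, neuromorphic computing, and biologically plausible
plasticity.

## The model

**Neurons and coding.** Inputs are rate-coded: each channel spikes as a
Poisson process with rate proportional to feature intensity, and every
rate vector is L2-normalized to one spike per time unit (fixing the time
scale). Output neurons are leaky integrate-and-fire units,

&nbsp;&nbsp;&nbsp;&nbsp; v̇ = −v/τ_mem,&nbsp;&nbsp; τ_mem = 15,

receiving delta-spike synapses (potential jumps by w_ij), firing on
v ≥ v_th and resetting to 0, with hard winner-take-all lateral
inhibition. Before the first fire the membrane is a shot-noise process
with closed-form moments

&nbsp;&nbsp;&nbsp;&nbsp; E[V(t)] = τ_mem (w·λ)(1 − e^(−t/τ_mem)),&nbsp;&nbsp;
Var[V(t)] = ½ τ_mem (λ·w∘²)(1 − e^(−2t/τ_mem)),

so for unit-norm aligned vectors the steady-state mean is τ_mem = 15 —
which is why the static thresholds live in 13.5–14.25 (the `theory`
module checks these formulas against Monte-Carlo simulation).

**Learning.** One-sided STDP evaluated at post-synaptic fires, stabilized
by tying the anti-Hebbian offset to the weight (an Oja-style correction):

&nbsp;&nbsp;&nbsp;&nbsp; Δw = α (pre/τ_pre − w),&nbsp;&nbsp; τ_pre = 200,

with each weight capped below a fixed bound before L2 renormalization of
the weight vector. At α = 1 this rule *replaces* the weight vector with
the current input direction (one-shot adoption); at α = 0.01 it slowly
refines a neuron toward the center of the cluster it fires for.

**Controlled forgetting.** A dopaminergic unit with resting potential
**above** its threshold (v_rest = 2, v_th = 1, τ_d = 200/ln 2) charges up
and self-fires after 200 time units — unless output spikes knock it down.
It therefore fires exactly when nothing recognizes the current input.
When it fires it boosts every learning rate to 1 and stimulates firing
through trained *dopaminergic weights* d_j, which are depressed
multiplicatively whenever neuron j fires and renormalized: the most
stimulated neuron is always a least-used one, so novel information
overwrites the least valuable representation, in one shot, in isolation.

## Worked example

`examples/lifelong_learning.py` trains on four synthetic classes (three
angular clusters each, MNIST-like geometry from the built-in generator)
presented disjointly, evaluating the frozen network after every task:

```
cfn          accuracy per stage: 100.0% -> 100.0% -> 100.0% -> 100.0%   (worst drop 0.0%)
no_dopamine  accuracy per stage: 100.0% -> 50.0% -> 33.3% -> 25.0%   (worst drop 50.0%)
```

The no-dopamine network keeps reusing its already-trained neurons (they
stay angularly closest to each new class) and overwrites old classes —
accuracy decays like 1/k, i.e. it only ever knows the current class. The
CFN adopts each novel cluster into a fresh neuron and loses nothing.

`examples/novelty_detection.py` shows the mechanism itself:

```
dopamine fired at t = 200.00 (expected 200: its rise time)
neurons whose weights changed: [0] (exactly one)
cosine(adopted weights, novel input) = 0.9913
```

Other examples: `membrane_statistics.py` (closed-form vs simulated
moments), `stdp_stability.py` (stabilized vs static-offset STDP),
`mnist_disjoint.py` (the same protocol on real MNIST IDX files, if you
have them locally — hours of CPU).

A thin CLI wraps the library: `cfnet train|eval|sweep|synth|theory-check`
(see `cfnet --help`).

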