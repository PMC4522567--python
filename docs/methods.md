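# Methods

`stdpnet` simulates a two-layer spiking network that learns to classify
rate-coded intensity images without labels.  This note documents the model,
its parameters, the numerical scheme, the synthetic benchmark the package
ships, and the design choices that were genuinely open.

## Neuron model

All neurons are conductance-based leaky integrate-and-fire units.  In
leak-normalized form the membrane voltage obeys

    tau_m dV/dt = (E_rest − V) + g_e (E_exc − V) + g_i (E_inh − V)

with dimensionless conductances `g_e`, `g_i` (multiples of the leak
conductance) that jump by the synaptic weight on each presynaptic spike and
decay as `tau_ge dg_e/dt = −g_e` (likewise `g_i`).  A neuron fires when
`V > v_thresh + theta` (strict; ties do not fire), resets to `v_reset`, and
is refractory for `t_refrac`.  Because the drive enters through conductances,
`V` can never exceed `E_exc` — this saturation is what ultimately bounds
firing rates when the adaptive threshold grows.

Physical inhibitory strengths quoted in nS map to leak units through a
configurable leak-conductance scale; the reference configuration stores the
lateral-inhibition weight directly in leak units.

Reference parameters (every one a config field, none a constant):

| parameter | excitatory | inhibitory | unit |
|---|---|---|---|
| E_rest    | −65 | −60 | mV |
| E_exc     | 0   | 0   | mV |
| E_inh     | −100| −85 | mV |
| tau_m     | 100 | 10  | ms |
| v_thresh  | −52 | −40 | mV |
| v_reset   | −65 | −45 | mV |
| t_refrac  | 5   | 2   | ms |
| tau_ge / tau_gi | 1 / 2 | 1 / 2 | ms |

The excitatory membrane constant is deliberately long (100 ms, vs the
10–20 ms typical of cortical neurons): the input is rate-coded, and at the
63.75 Hz peak rate a 100 ms integrator averages ≈6.4 input spikes where a
20 ms one sees ≈1.3, so single noise spikes would otherwise dominate.

## Architecture

784 Poisson input units (one per pixel) project all-to-all through the
plastic weight matrix onto `n_exc` excitatory neurons.  Each excitatory
neuron drives a dedicated inhibitory partner one-to-one; each inhibitory
neuron projects back to every excitatory neuron *except* its partner.  One
excitatory spike therefore inhibits all competitors — a soft winner-take-all.
The exc→inh weight is computed at build time by bisection on a short
single-neuron simulation: the smallest weight that relays one spike within
2 ms, times a safety margin (default 3×).  This realizes the intended
"one spike in, one spike out" relay for whatever inhibitory cell parameters
are configured, instead of hard-coding a number.

Spikes between the layers travel with a one-time-step delay in each
direction; zero-delay loops are ill-defined in a clock-driven scheme.
Input spikes reach the excitatory conductances within the same step.

## Plasticity

Only the input→excitatory synapses learn.  Learning is trace-based: each
input carries a presynaptic trace `x_pre` (+1 per spike, exponential decay,
tau 20 ms); the pre-and-post and triplet rules add postsynaptic traces
(fast tau 20 ms, slow tau 125 ms).  Four interchangeable rules:

- **powerlaw** (post events): `dw = eta (x_pre − x_tar) (w_max − w)^mu`.
  The target trace `x_tar` depresses synapses from inputs that rarely
  precede firing, disconnecting irrelevant pixels.
- **expdep** (post events):
  `dw = eta_post (x_pre e^(−beta w) − x_tar e^(−beta (w_max − w)))`.
- **prepost**: pre events depress by `eta_pre x_post w^mu`; post events
  potentiate as the power-law form with `eta_post`.
- **triplet**: pre events depress by `A2m x_post`; post events potentiate by
  `x_pre (A2p + A3p x_post_slow)`, the slow trace sampled before its own
  increment.  The `A3p` term makes potentiation grow with postsynaptic
  rate — the rule's signature frequency dependence.

Coincident-event semantics (deterministic): within a step, pre events are
processed before post events; a post event reads `x_pre` *including*
same-step pre increments; a pre event reads `x_post` *excluding* same-step
post increments.

Defaults: `eta = eta_post = 1e−2`, `eta_pre = 1e−4`, `x_tar = 0.4`,
`mu = 0.9` (1.0 for prepost), `beta = 3`, `w_max = 1`.  Initial weights are
uniform in `[0, 0.3] w_max` (seeded) — competition requires broken symmetry.

**Triplet amplitudes.**  The defaults are `A2p = 6e−3`, `A2m = 5e−3`,
`A3p = 6.2e−3`.  Published fits of the triplet rule to visual-cortex data
set the pair-potentiation amplitude to ~0, letting the triplet term carry
all potentiation.  That balance assumes sustained postsynaptic rates.  In
the scaled-down regime this package targets (tens of neurons, often a
single spike per neuron per presentation) a near-zero pair term is
structurally unstable: a neuron that fires once gains nothing (its slow
trace is empty at its own spike) yet pays pair depression on every
subsequent input spike, so weight mass drains from exactly the pixels that
drive the neuron, firing drops further, and the network dies.  A pair
potentiation comparable to the pair depression bootstraps single-spike
learning while preserving the triplet term's frequency dependence.  All
three amplitudes are configuration fields.

**Bounds and normalization.**  Weights are clipped to `[0, w_max]` after
every update.  Before each presentation the incoming weights of every
excitatory neuron are divisively rescaled to sum to `norm_target`
(default 78.4 = 10% of the input count), then re-clipped.  Normalization is
essential for the weight-independent triplet rule and is enabled for all
rules by default (`normalize_every_presentation`): it enforces equal
synaptic resource use, which at small network sizes materially improves the
balance of neurons across classes for every rule.

## Homeostasis

Each excitatory neuron's threshold offset `theta` grows by `theta_plus` per
spike and decays with `tau_theta` (default 1e7 ms — effectively a spike
counter on training timescales).  Frequent winners become harder to drive,
so competition rotates and firing rates equalize.  During evaluation
`theta` is frozen (no decay, no increments) but still raises the threshold;
after the rest phase it is retained, not reset.

The homeostatic schedule must scale with network size: fewer neurons means
each neuron wins proportionally more presentations, so theta accumulates
faster, and at `tau_theta = 1e7` ms (no effective decay) it drifts linearly
until the threshold approaches the conductance-saturation ceiling and the
network falls silent.  The small-network preset (`n_exc ≤ 50`) therefore
shortens the homeostatic memory to `tau_theta = 1e6` ms with
`theta_plus = 0.05` and `w_inh_to_exc = 8`: theta then has a stable
equilibrium (observed ≈ 35–40 mV over 3000-presentation runs, with ample
headroom below the ≈ 51 mV ceiling at the maximal retry boost) while still
spanning thousands of presentations of memory.  The ~100-neuron reference
scale keeps `17.0 / 0.05 / 1e7`.

## Encoding and protocol

Pixel intensities (0–255) divide by 4 to give Poisson rates in 0–63.75 Hz,
sampled as independent Bernoulli(rate·dt) events per 0.5 ms step (peak
probability ≈ 0.032, well inside the thinning regime).  Each image is
presented for 350 ms; if the excitatory layer fires fewer than 5 spikes,
the whole rate map is rescaled so its maximum rises by 32 Hz (preserving
pixel proportionality) and the image is re-presented with a fresh Poisson
draw, after a rest phase; a configurable cap (20) turns a dead input (e.g.
an all-zero image, which rescaling cannot rescue) into an explicit fault.
Between presentations a 150 ms input-free rest lets all fast variables
decay; once the network is quiescent the remainder of the rest is completed
with the exact closed-form decays.  Plasticity, when enabled, applies on
every retry attempt.

Training uses no labels.  Afterwards, learning is switched off, thresholds
frozen, and each neuron is assigned the class with its highest mean spike
count over a labeled assignment pass (ties to the lowest class index; a
silent neuron gets class 0 with a warning).  A test image is classified by
the class whose assigned neurons fired most on average — a pure rate vote.
The retry boost remains active at test time (configurable).  Training
stability can be monitored without extra passes via trailing blocks: each
block of training responses is classified with labels assigned from the
preceding block.

## Numerics

Clock-driven integration at `dt = 0.5` ms (configurable).  Conductances,
traces, and theta use their exact per-step exponential factors;
the membrane uses the exponential-Euler update
`V ← V∞ + (V − V∞) e^(−dt (1+g_e+g_i)/tau_m)` with `V∞` the instantaneous
fixed point — unconditionally stable at the long excitatory time constant.
Between spikes the simulated decays therefore match the closed forms to
float rounding (≲1e−12 relative over 1000 steps).  Threshold comparison is
strict; equality does not fire.  Non-finite state trips an explicit fault
naming the offending neuron.

## Synthetic benchmark

The generator draws class-structured images from five binary templates —
vertical bar, horizontal bar, the two diagonals, and a double horizontal
bar — with template pixels at intensity 255, a uniform ±2 px translation
jitter, and 1% per-pixel salt noise.  Design constraints: template pixel
masses are balanced (80/80/72/72/88) so classes compete for neurons on
equal stimulus energy, and pairwise template cosines stay below 0.5 (the
separability guard), which the generator validates.  Thin closed outlines
(e.g. a box) were rejected during design: under ±2 px jitter their
blurred receptive fields cannot exceed ≈0.67 cosine against the template,
making recovery unmeasurable rather than unlearned.

Because stimuli are templates at jittered offsets, a prototype is only
identifiable up to that translation group; recovery is therefore scored as
the best cosine between a receptive field and any copy of the template
shifted within the jitter range.  Trained networks visibly tile the jitter
offsets with specialized neurons.

What the fixture does *not* emulate about real handwritten digits:
within-class shape variability beyond translation, stroke-thickness and
slant variation, grayscale edges (templates are binary), and class overlap
structure.  Passing the synthetic recovery tests shows the mechanisms —
competition, homeostasis, trace-based learning — interact correctly at
small scale; it does not certify benchmark accuracy on real digit data,
which requires the documented full-scale script (`scripts/run_mnist.py`)
and external IDX files.

Default experiment sizes (chosen as the package's scaled-down study
conditions): 5 classes, `n_exc = 25`, 600 training presentations, 250
assignment and 150 test presentations; the stability experiment extends
training to 3000 presentations with 300-presentation trailing blocks.

## Known limitations

- Bernoulli-per-step thinning approximates Poisson; exact at the ≲3%
  per-step probabilities used, degraded if `rate·dt` approaches 1
  (rejected at ≥1).
- The one-step inter-layer delay makes the effective inhibition latency
  2 steps (1 ms at the default dt); inhibition strengths are calibrated at
  `dt = 0.5` ms and should be revisited if dt changes substantially.
- `theta` has no true equilibrium at the default `tau_theta` (1e7 ms); over
  runs much longer than ~10^4 presentations at small `n_exc` the threshold
  drift would eventually silence the network unless `tau_theta` is lowered
  or `theta_plus` reduced.
- A neuron population is homogeneous; no parameter heterogeneity within a
  layer.
- No inhibitory-synapse plasticity, no structural plasticity, no
  multi-compartment or adaptive-exponential neuron variants, no
  event-driven exact simulation, and no reduced (e.g. 4:1) inhibitory pool.
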