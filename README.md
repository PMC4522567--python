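# stdpnet

Unsupervised classification with a spiking neural network: conductance-based
leaky integrate-and-fire neurons, trace-based spike-timing-dependent
plasticity (STDP), soft winner-take-all lateral inhibition, and an adaptive
firing threshold.  The network learns prototype receptive fields from
rate-coded intensity images **without ever seeing a label**; labels are used
only afterwards, to name each neuron by the class it responds to most, and
classification is a plain rate vote over those assignments — no classifier
is trained on top of the spikes.

The package is aimed at computational-neuroscience practitioners who want a
tested, parameter-transparent reimplementation of this architecture: to
probe which mechanisms carry the computation (competition, homeostasis,
weight dependence), to compare STDP rule variants under identical
conditions, or to prototype before committing to neuromorphic hardware.

## Model

Membrane dynamics (leak-normalized, conductance-based):

    tau_m dV/dt = (E_rest − V) + g_e (E_exc − V) + g_i (E_inh − V)
    tau_ge dg_e/dt = −g_e          tau_gi dg_i/dt = −g_i

A spike at `V > v_thresh + theta` resets `V` and increments the adaptive
threshold `theta` (intrinsic-plasticity homeostasis); `theta` decays on a
very slow time scale, so busy neurons handicap themselves and competition
rotates.  Input pixels become Poisson spike trains at `intensity/4` Hz
(0–63.75 Hz), presented 350 ms each with 150 ms rest; images that evoke
fewer than 5 output spikes are re-presented with the peak rate boosted by
32 Hz until the network responds.

Input→excitatory synapses learn by one of four trace-based STDP rules,
selected by `rule_id`:

| rule | post-spike update | pre-spike update |
|---|---|---|
| `powerlaw` | `η (x_pre − x_tar)(w_max − w)^μ` | — |
| `expdep`   | `η_post (x_pre e^{−βw} − x_tar e^{−β(w_max−w)})` | — |
| `prepost`  | `η_post (x_pre − x_tar)(w_max − w)^μ` | `−η_pre x_post w^μ` |
| `triplet`  | `x_pre (A2⁺ + A3⁺ x̄_post^slow)` | `−A2⁻ x_post` |

`x_pre`/`x_post` are exponentially decaying spike traces (+1 per spike).
Divisive weight normalization keeps each neuron's summed incoming weight at
a fixed target, enforcing equal resource use.  See `docs/methods.md` for
every parameter, unit, and default, and for the reasoning behind each
numerical choice.

## Worked example

Train a 25-neuron network on the built-in 5-class synthetic fixture (bars,
diagonals, and a double bar, jittered and noisy), then evaluate:

    stdpnet train --n-exc 25 --rule powerlaw --presentations 600 \
        --seed 0 --out runs/demo
    stdpnet evaluate --weights runs/demo/weights.npz --n-exc 25 \
        --seed 0 --out runs/demo
    stdpnet inspect --weights runs/demo/weights.npz --out runs/demo

which prints (about a minute of CPU in total)

    trained 600 presentations -> runs/demo/weights.npz
    accuracy 1.000 -> runs/demo/evaluation.json
    {
      "meta": { "rule_id": "powerlaw", "n_exc": 25, "seed": 0,
                "n_presentations": 600 },
      "w_mean": 0.10001784816948242,
      "w_max": 0.9946779479281675,
      "col_sum_mean": 78.41399296487423,
      "theta_mean": 27.92685977195447,
      "figure": "runs/demo/receptive_fields.png"
    }

Reading the numbers: `accuracy 1.000` is the rate-vote test accuracy on 150
held-out images — after 600 unlabeled presentations the 25 neurons have
split into per-class groups, and `runs/demo/receptive_fields.png` shows each
neuron's 28×28 incoming-weight image as a sharpened copy of one template at
one jitter offset.  `col_sum_mean ≈ 78.4` is the divisive-normalization
target (each neuron uses the same total synaptic resource); `theta_mean ≈
28` mV is the accumulated homeostatic threshold, the price frequent winners
paid to keep the competition fair.  The `evaluation.json` report also
contains the confusion matrix and spike-sparsity statistics (typically
~15–20 spikes per presentation, nearly all from neurons of the correct
class).

The same pipeline is available as a library:

```python
from stdpnet.experiments import run_synthetic_experiment
r = run_synthetic_experiment("triplet", n_exc=25, n_train=600, seed=0)
print(r["accuracy"], r["template_match"])
```

## Full-scale digit benchmark

`scripts/run_mnist.py` reproduces the 100-excitatory-neuron configuration
on the standard 60k/10k handwritten-digit IDX files (which you download
yourself); it needs hours of CPU and is deliberately not part of the test
suite.  `stdpnet train --data idx:IMAGES,LABELS ...` accepts the same files.

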