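"""Trace-based STDP rules for the input -> excitatory synapse matrix.

Weight dynamics are computed from synaptic traces rather than full spike
histories: each input neuron carries a presynaptic trace ``x_pre`` that jumps
by 1 on every presynaptic spike and decays exponentially otherwise; the
pre-and-post and triplet rules additionally keep postsynaptic traces.  Traces
are sampled at spike events to evaluate one of four interchangeable rules:

``powerlaw``
    On a postsynaptic spike, dw = eta * (x_pre - x_tar) * (w_max - w)**mu.
    The target trace ``x_tar`` disconnects inputs that rarely precede firing.
``expdep``
    On a postsynaptic spike,
    dw = eta_post * (x_pre*exp(-beta*w) - x_tar*exp(-beta*(w_max - w))).
``prepost``
    On a presynaptic spike, dw = -eta_pre * x_post * w**mu (depression);
    on a postsynaptic spike, dw = eta_post * (x_pre - x_tar) * (w_max - w)**mu.
``triplet``
    Pair/triplet rule with a slow postsynaptic trace: a presynaptic spike
    depresses by A2_minus * x_post; a postsynaptic spike potentiates by
    x_pre * (A2_plus + A3_plus * x_post_slow), the slow trace sampled just
    before its own increment.  The rule has no weight dependence, so weights
    are kept bounded by divisive normalization and clipping.

Event-time trace semantics (deterministic tie-break for coincident events):
a postsynaptic event reads ``x_pre`` *including* any same-step presynaptic
increment; a presynaptic event reads ``x_post`` *excluding* same-step
postsynaptic increments.  Within a step, presynaptic events are processed
before postsynaptic ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RULE_IDS",
    "RuleParams",
    "TraceState",
    "SynapseMatrix",
    "WeightBoundsError",
    "default_rule_params",
    "decay_traces",
    "on_pre_spike",
    "on_post_spike",
    "dw_powerlaw",
    "dw_expdep",
    "dw_prepost_pre",
    "dw_prepost_post",
    "dw_triplet",
    "normalize_divisive",
    "clip_weights",
    "init_weights",
    "replay_events",
]

RULE_IDS = ("powerlaw", "expdep", "prepost", "triplet")

_BOUND_SLACK = 1e-12  # float tolerance when validating 0 <= w <= w_max


class WeightBoundsError(ValueError):
    """A weight passed to a rule lies outside [0, w_max]."""


@dataclass(frozen=True)
class RuleParams:
    """Parameters of one STDP rule; only the fields its rule reads matter.

    Learning rates and amplitudes are per-event weight changes in units of
    ``w_max``; time constants in ms.  ``norm_target`` is the per-neuron
    incoming weight sum restored by divisive normalization.
    """

    rule_id: str = "powerlaw"
    eta: float = 1e-2         # learning rate of the single-rate rules (Eq.-3 form)
    eta_pre: float = 1e-4     # presynaptic-event learning rate (prepost)
    eta_post: float = 1e-2    # postsynaptic-event learning rate (expdep, prepost)
    x_tar: float = 0.4        # target presynaptic trace at a postsynaptic spike
    mu: float = 0.9           # power-law weight-dependence exponent
    beta: float = 3.0         # exponential weight-dependence strength
    w_max: float = 1.0        # weight ceiling
    tau_pre: float = 20.0     # presynaptic trace time constant
    tau_post: float = 20.0    # fast postsynaptic trace time constant
    tau_post_slow: float = 125.0  # slow postsynaptic (triplet) trace time constant
    a2_plus: float = 6e-3     # triplet pair potentiation amplitude
    a2_minus: float = 5e-3    # triplet pair depression amplitude
    a3_plus: float = 6.2e-3   # triplet (frequency-dependent) potentiation amplitude
    norm_target: float = 78.4 # divisive-normalization column sum (10% of 784)

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_IDS:
            raise ValueError(f"unknown rule_id {self.rule_id!r}; expected one of {RULE_IDS}")
        for name in ("eta", "eta_pre", "eta_post", "x_tar", "mu", "beta",
                     "a2_plus", "a2_minus", "a3_plus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.w_max <= 0 or self.norm_target <= 0:
            raise ValueError("w_max and norm_target must be positive")
        for name in ("tau_pre", "tau_post", "tau_post_slow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def uses_post_trace(self) -> bool:
        return self.rule_id in ("prepost", "triplet")


def default_rule_params(rule_id: str, **overrides) -> RuleParams:
    """Reference parameter set for a rule; per-rule defaults differ only in mu."""
    base = dict(rule_id=rule_id)
    if rule_id == "prepost":
        base["mu"] = 1.0
    base.update(overrides)
    return RuleParams(**base)


@dataclass
class TraceState:
    """Exponentially decaying spike traces for one synapse matrix."""

    x_pre: np.ndarray                 # per input neuron
    x_post: np.ndarray                # fast trace per excitatory neuron
    x_post_slow: np.ndarray           # slow (triplet) trace per excitatory neuron
    tau_pre: float = 20.0
    tau_post: float = 20.0
    tau_post_slow: float = 125.0

    @classmethod
    def zeros(cls, n_pre: int, n_post: int, p: RuleParams) -> "TraceState":
        return cls(
            x_pre=np.zeros(n_pre),
            x_post=np.zeros(n_post),
            x_post_slow=np.zeros(n_post),
            tau_pre=p.tau_pre,
            tau_post=p.tau_post,
            tau_post_slow=p.tau_post_slow,
        )


@dataclass
class SynapseMatrix:
    """Dense input -> excitatory weight matrix with a hard ceiling."""

    w: np.ndarray       # shape (n_input, n_exc)
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if self.w.ndim != 2:
            raise ValueError("weight matrix must be 2-D (n_input, n_exc)")
        if np.any(self.w < -_BOUND_SLACK) or np.any(self.w > self.w_max + _BOUND_SLACK):
            raise WeightBoundsError("initial weights outside [0, w_max]")


def init_weights(n_input: int, n_exc: int, rng: np.random.Generator,
                 w_max: float = 1.0, scale: float = 0.3) -> np.ndarray:
    """Uniform random initial weights in [0, scale*w_max] (symmetry breaking)."""
    return rng.random((n_input, n_exc)) * scale * w_max


# ---------------------------------------------------------------------------
# trace bookkeeping


def decay_traces(t: TraceState, dt: float) -> TraceState:
    """Decay every trace by its own exact exponential factor over dt ms."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    t.x_pre *= np.exp(-dt / t.tau_pre)
    t.x_post *= np.exp(-dt / t.tau_post)
    t.x_post_slow *= np.exp(-dt / t.tau_post_slow)
    return t


def on_pre_spike(t: TraceState, which_inputs) -> TraceState:
    """Increment presynaptic traces by 1 (once per neuron per step)."""
    idx = np.unique(np.asarray(which_inputs, dtype=np.intp))
    if idx.size and (idx[0] < 0 or idx[-1] >= t.x_pre.shape[0]):
        raise IndexError("input index out of range")
    t.x_pre[idx] += 1.0
    return t


def on_post_spike(t: TraceState, which_neurons) -> TraceState:
    """Increment fast and slow postsynaptic traces by 1."""
    idx = np.unique(np.asarray(which_neurons, dtype=np.intp))
    if idx.size and (idx[0] < 0 or idx[-1] >= t.x_post.shape[0]):
        raise IndexError("neuron index out of range")
    t.x_post[idx] += 1.0
    t.x_post_slow[idx] += 1.0
    return t


# ---------------------------------------------------------------------------
# the four rules (elementwise; scalars or arrays broadcast)


def _check_bounds(w, w_max: float) -> None:
    w = np.asarray(w)
    if np.any(w < -_BOUND_SLACK) or np.any(w > w_max + _BOUND_SLACK):
        raise WeightBoundsError(f"weight outside [0, {w_max}]")


def dw_powerlaw(x_pre, w, p: RuleParams):
    """Post-event update with power-law weight dependence."""
    _check_bounds(w, p.w_max)
    return p.eta * (x_pre - p.x_tar) * np.maximum(p.w_max - w, 0.0) ** p.mu


def dw_expdep(x_pre, w, p: RuleParams):
    """Post-event update with exponential weight dependence."""
    _check_bounds(w, p.w_max)
    return p.eta_post * (
        x_pre * np.exp(-p.beta * w) - p.x_tar * np.exp(-p.beta * (p.w_max - w))
    )


def dw_prepost_pre(x_post, w, p: RuleParams):
    """Pre-event depression of the pre-and-post rule (always <= 0)."""
    _check_bounds(w, p.w_max)
    return -p.eta_pre * x_post * np.maximum(w, 0.0) ** p.mu


def dw_prepost_post(x_pre, w, p: RuleParams):
    """Post-event potentiation of the pre-and-post rule (same form as powerlaw)."""
    _check_bounds(w, p.w_max)
    return p.eta_post * (x_pre - p.x_tar) * np.maximum(p.w_max - w, 0.0) ** p.mu


def dw_triplet(event: str, t: TraceState, p: RuleParams, post_neuron: int | None = None):
    """Triplet-rule weight change for one event.

    ``event='pre'``: returns the depression per postsynaptic neuron (a vector
    over the excitatory population, identical for every spiking input).
    ``event='post'``: returns the potentiation per input synapse of
    ``post_neuron``, with the slow postsynaptic trace sampled before its own
    increment (so callers must evaluate this before :func:`on_post_spike`).
    """
    if event == "pre":
        return -p.a2_minus * t.x_post
    if event == "post":
        if post_neuron is None:
            raise ValueError("post event requires the index of the spiking neuron")
        return t.x_pre * (p.a2_plus + p.a3_plus * t.x_post_slow[post_neuron])
    raise ValueError(f"event must be 'pre' or 'post', got {event!r}")


# ---------------------------------------------------------------------------
# weight-matrix maintenance


def normalize_divisive(w: np.ndarray, norm_target: float) -> np.ndarray:
    """Scale each excitatory neuron's incoming weights to sum to norm_target.

    Operates in place on the (n_input, n_exc) matrix and returns it.  Columns
    with zero sum cannot be rescaled; they are left unchanged with a warning.
    Relative proportions within a column are preserved, enforcing equal
    synaptic resource use across neurons.
    """
    sums = w.sum(axis=0)
    zero = sums <= 0.0
    if np.any(zero):
        warnings.warn(
            f"divisive normalization skipped {int(zero.sum())} zero-sum column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    scale = np.ones_like(sums)
    np.divide(norm_target, sums, out=scale, where=~zero)
    w *= scale
    return w


def clip_weights(w: np.ndarray, w_max: float = 1.0) -> np.ndarray:
    """Clamp weights elementwise to [0, w_max], in place."""
    np.clip(w, 0.0, w_max, out=w)
    return w


# ---------------------------------------------------------------------------
# scripted replay (the incremental machinery on an explicit event list)


def replay_events(
    events,
    n_pre: int,
    n_post: int,
    w0: np.ndarray,
    p: RuleParams,
    dt: float = 0.5,
):
    """Run the incremental trace/weight updates over a scripted event list.

    ``events`` is an iterable of ``(step, kind, index)`` with ``kind`` in
    {'pre', 'post'}; steps are integers in units of ``dt``.  Events are
    processed in step order with the same intra-step ordering as the network
    simulation (pre before post).  Returns ``(w, snapshots)`` where
    ``snapshots`` is a list of ``(step, kind, index, w_copy)`` taken after
    each event's update — the hook used to cross-check the trace bookkeeping
    against full-history recomputation.
    """
    w = np.array(w0, dtype=np.float64, copy=True)
    if w.shape != (n_pre, n_post):
        raise ValueError("w0 shape mismatch")
    traces = TraceState.zeros(n_pre, n_post, p)
    by_step: dict[int, list] = {}
    for step, kind, index in events:
        by_step.setdefault(int(step), []).append((kind, int(index)))
    snapshots = []
    last = max(by_step) if by_step else -1
    for step in range(last + 1):
        decay_traces(traces, dt)
        todo = by_step.get(step, [])
        pre_events = [i for k, i in todo if k == "pre"]
        post_events = [i for k, i in todo if k == "post"]
        for i in pre_events:
            if p.rule_id == "prepost":
                w[i, :] += dw_prepost_pre(traces.x_post, w[i, :], p)
            elif p.rule_id == "triplet":
                w[i, :] += dw_triplet("pre", traces, p)
            clip_weights(w[i, :], p.w_max)
            on_pre_spike(traces, [i])
            snapshots.append((step, "pre", i, w.copy()))
        # all simultaneous post events read traces before any post increment
        for j in post_events:
            if p.rule_id == "powerlaw":
                w[:, j] += dw_powerlaw(traces.x_pre, w[:, j], p)
            elif p.rule_id == "expdep":
                w[:, j] += dw_expdep(traces.x_pre, w[:, j], p)
            elif p.rule_id == "prepost":
                w[:, j] += dw_prepost_post(traces.x_pre, w[:, j], p)
            else:
                w[:, j] += dw_triplet("post", traces, p, post_neuron=j)
            clip_weights(w[:, j], p.w_max)
            snapshots.append((step, "post", j, w.copy()))
        if post_events:
            on_post_spike(traces, post_events)
    return w, snapshots
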