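"""Conductance-based leaky integrate-and-fire population dynamics.

The membrane voltage of each neuron follows the leak-normalized equation

    tau_m * dV/dt = (E_rest - V) + g_e * (E_exc - V) + g_i * (E_inh - V)

where ``g_e`` and ``g_i`` are dimensionless synaptic conductances (multiples
of the leak conductance) that jump by the synaptic weight on each presynaptic
spike and otherwise decay exponentially with their own time constants,

    tau_ge * dg_e/dt = -g_e,        tau_gi * dg_i/dt = -g_i.

A neuron fires when V exceeds ``v_thresh + theta``; V is then reset and the
neuron becomes refractory.  ``theta`` is a per-neuron adaptive threshold
offset (intrinsic-plasticity homeostasis): it grows by a fixed increment on
every spike and decays exponentially on a very slow time scale, so neurons
that fire often become harder to drive and the population's firing rates
equalize.

Integration is clock-driven exponential Euler, one exact exponential update
per state variable per time step: conductances and theta have exact
closed-form solutions between spikes, and the membrane uses the
effective-time-constant update

    V <- V_inf + (V - V_inf) * exp(-dt * (1 + g_e + g_i) / tau_m)

with V_inf the algebraic fixed point of the membrane equation at the current
conductances.  This is unconditionally stable at the long excitatory membrane
time constant (100 ms) used for rate estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "HomeostasisParams",
    "NeuronPopulationState",
    "NumericalFault",
    "step_population",
    "decay_theta",
    "deliver_spikes",
]


class NumericalFault(FloatingPointError):
    """A state variable became non-finite; carries the offending neuron index."""

    def __init__(self, variable: str, index: int):
        self.variable = variable
        self.index = index
        super().__init__(f"non-finite {variable} at neuron index {index}")


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of one LIF population.  Voltages in mV, times in ms.

    Defaults are the excitatory cell of the reference configuration; see
    :func:`stdpnet.config.reference_config` for the inhibitory counterpart.
    """

    e_rest: float = -65.0     # resting / leak reversal potential (mV)
    e_exc: float = 0.0        # excitatory synaptic reversal potential (mV)
    e_inh: float = -100.0     # inhibitory synaptic reversal potential (mV)
    tau_m: float = 100.0      # membrane time constant (ms)
    v_thresh: float = -52.0   # base firing threshold (mV)
    v_reset: float = -65.0    # post-spike reset voltage (mV)
    t_refrac: float = 5.0     # absolute refractory period (ms)
    tau_ge: float = 1.0       # excitatory conductance time constant (ms)
    tau_gi: float = 2.0       # inhibitory conductance time constant (ms)

    def __post_init__(self) -> None:
        if not (self.e_inh < self.e_rest < self.v_thresh < self.e_exc):
            raise ValueError(
                "require E_inh < E_rest < v_thresh < E_exc, got "
                f"{self.e_inh}, {self.e_rest}, {self.v_thresh}, {self.e_exc}"
            )
        if self.v_reset > self.v_thresh:
            raise ValueError("v_reset must not exceed v_thresh")
        for name in ("tau_m", "tau_ge", "tau_gi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_refrac < 0:
            raise ValueError("t_refrac must be non-negative")


@dataclass(frozen=True)
class HomeostasisParams:
    """Adaptive-threshold (intrinsic plasticity) parameters.

    ``theta_plus`` is added to a neuron's threshold offset theta on every
    spike; theta decays with time constant ``tau_theta`` (by default far
    longer than a training run, so theta is effectively a spike counter).
    With ``enabled`` False theta is frozen: no decay and no increments, but
    its current value still raises the firing threshold — this is how the
    threshold is fixed during evaluation.
    """

    theta_plus: float = 0.05  # per-spike threshold increment (mV)
    tau_theta: float = 1e7    # theta decay time constant (ms)
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.theta_plus < 0:
            raise ValueError("theta_plus must be non-negative")
        if self.tau_theta <= 0:
            raise ValueError("tau_theta must be positive")


@dataclass
class NeuronPopulationState:
    """Mutable per-neuron state arrays of one population."""

    v: np.ndarray                 # membrane voltage (mV)
    g_e: np.ndarray               # excitatory conductance (leak units)
    g_i: np.ndarray               # inhibitory conductance (leak units)
    theta: np.ndarray             # adaptive threshold offset (mV)
    refrac_remaining: np.ndarray  # time left in refractory period (ms)
    spiked: np.ndarray = field(default=None)  # bool mask set by step_population

    def __post_init__(self) -> None:
        n = self.v.shape[0]
        for name in ("g_e", "g_i", "theta", "refrac_remaining"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"state array {name} has mismatched length")
        if self.spiked is None:
            self.spiked = np.zeros(n, dtype=bool)

    @classmethod
    def resting(cls, n: int, p: NeuronParams) -> "NeuronPopulationState":
        """All neurons at rest with zero conductances and zero theta."""
        return cls(
            v=np.full(n, p.e_rest, dtype=np.float64),
            g_e=np.zeros(n),
            g_i=np.zeros(n),
            theta=np.zeros(n),
            refrac_remaining=np.zeros(n),
        )

    def __len__(self) -> int:
        return self.v.shape[0]


def decay_theta(theta, tau_theta: float, dt: float):
    """Exact exponential decay of the adaptive threshold over ``dt`` ms."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return theta * math.exp(-dt / tau_theta)


def deliver_spikes(
    state: NeuronPopulationState,
    exc_input: np.ndarray | float,
    inh_input: np.ndarray | float,
) -> NeuronPopulationState:
    """Instantaneous conductance increments from arriving spikes.

    Each presynaptic spike raises the target conductance by the synaptic
    weight; increments must be non-negative (weights are conductances).
    Modifies ``state`` in place and returns it.
    """
    if np.any(np.asarray(exc_input) < 0) or np.any(np.asarray(inh_input) < 0):
        raise ValueError("conductance increments must be non-negative")
    state.g_e += exc_input
    state.g_i += inh_input
    return state


def _check_finite(state: NeuronPopulationState) -> None:
    # cheap screen first (a non-finite entry poisons the sum), then locate
    total = float(state.v.sum()) + float(state.g_e.sum()) + float(state.g_i.sum())
    if math.isfinite(total):
        return
    for name in ("v", "g_e", "g_i"):
        arr = getattr(state, name)
        if not np.isfinite(arr).all():
            idx = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise NumericalFault(name, idx)


def step_population(
    state: NeuronPopulationState,
    p: NeuronParams,
    h: HomeostasisParams,
    dt: float,
) -> NeuronPopulationState:
    """Advance one population by one time step of ``dt`` ms (in place).

    Order of sub-updates within the step:

    1. refractory clocks tick down (floored at 0); neurons at 0 are active;
    2. active membranes take one exponential-Euler step at the current
       conductances (refractory membranes stay clamped at reset);
    3. conductances decay exactly; theta decays (when homeostasis enabled);
    4. active neurons with V strictly above ``v_thresh + theta`` spike:
       V := v_reset, refractory clock := t_refrac, theta += theta_plus.

    Ties at threshold do not fire.  Raises :class:`NumericalFault` if any
    state variable is non-finite after the update.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")

    rr = state.refrac_remaining
    rr -= dt
    np.maximum(rr, 0.0, out=rr)
    active = rr <= 0.0

    g_e, g_i, v = state.g_e, state.g_i, state.v
    g_tot = g_e + g_i
    g_tot += 1.0
    v_inf = g_e * p.e_exc
    v_inf += g_i * p.e_inh
    v_inf += p.e_rest
    v_inf /= g_tot
    g_tot *= -dt / p.tau_m
    decay = np.exp(g_tot, out=g_tot)
    if active.all():
        # v <- v_inf + (v - v_inf) * decay, in place
        v -= v_inf
        v *= decay
        v += v_inf
    else:
        v_new = v_inf + (v - v_inf) * decay
        v[active] = v_new[active]

    g_e *= math.exp(-dt / p.tau_ge)
    g_i *= math.exp(-dt / p.tau_gi)
    if h.enabled:
        state.theta *= math.exp(-dt / h.tau_theta)

    spiked = active & (state.v > p.v_thresh + state.theta)
    state.v[spiked] = p.v_reset
    state.refrac_remaining[spiked] = p.t_refrac
    if h.enabled:
        state.theta[spiked] += h.theta_plus
    state.spiked = spiked

    _check_finite(state)
    return state
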