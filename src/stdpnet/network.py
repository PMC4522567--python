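"""Two-layer competitive spiking network and its clock-driven run loop.

Architecture: an input layer of Poisson generators (one per pixel) projects
all-to-all through the plastic weight matrix onto a population of excitatory
LIF neurons.  Each excitatory neuron drives its own dedicated inhibitory
neuron through a strong fixed one-to-one synapse, and every inhibitory
neuron projects back onto all excitatory neurons *except* its partner.  An
excitatory spike therefore inhibits all competitors — a soft winner-take-all
circuit — while the adaptive threshold slowly handicaps frequent winners so
every neuron gets a chance to specialize.

Spike propagation between the layers uses a one-time-step synaptic delay in
each direction (zero-delay loops are ill-defined in a clock-driven scheme);
input spikes reach the excitatory conductances within the same step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from . import plasticity as pl
from .dynamics import (
    HomeostasisParams,
    NeuronParams,
    NeuronPopulationState,
    deliver_spikes,
    step_population,
)
from .encoding import present_with_retry

__all__ = [
    "NetworkConfig",
    "SpikeRecord",
    "Network",
    "build_network",
    "relay_weight",
    "train_network",
]

_FROZEN = HomeostasisParams(enabled=False)


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, fixed weights, timing, and protocol constants of one network."""

    n_input: int = 784
    n_exc: int = 100
    n_inh: int | None = None        # must equal n_exc; None means n_exc
    w_exc_to_inh: float | None = None  # None: computed at build time (relay guarantee)
    w_inh_to_exc: float = 17.0      # lateral inhibition strength (leak units)
    dt: float = 0.5                 # simulation time step (ms)
    presentation_ms: float = 350.0  # stimulus duration
    rest_ms: float = 150.0          # input-free phase between stimuli
    min_exc_spikes: int = 5         # minimum response before the retry boost
    rate_boost_hz: float = 32.0     # additive boost of the max input rate per retry
    intensity_divisor: float = 4.0  # intensity -> Hz conversion (255 -> 63.75 Hz)
    record_times: bool = False      # keep (neuron, t) spike events per presentation
    normalize_every_presentation: bool = True  # divisive normalization cadence
    relay_margin: float = 3.0       # safety factor on the computed exc->inh weight

    def __post_init__(self) -> None:
        n_inh = self.n_exc if self.n_inh is None else self.n_inh
        if n_inh != self.n_exc:
            raise ValueError("n_inh must equal n_exc (one-to-one exc->inh pairing)")
        if min(self.n_input, self.n_exc) <= 0:
            raise ValueError("population sizes must be positive")
        for name in ("dt", "presentation_ms", "rest_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.w_inh_to_exc < 0 or (self.w_exc_to_inh is not None and self.w_exc_to_inh < 0):
            raise ValueError("fixed weights must be non-negative")


@dataclass
class SpikeRecord:
    """Excitatory response to one presentation."""

    counts: np.ndarray                      # spikes per excitatory neuron
    times: list[tuple[int, float]] | None = None  # optional (neuron, t_ms) events

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")


def relay_weight(p_inh: NeuronParams, dt: float, margin: float = 3.0) -> float:
    """Smallest exc->inh weight that makes a single excitatory spike trigger
    the paired inhibitory neuron within 2 ms, times a safety margin.

    Found by bisection on a short single-neuron simulation of an impulse
    conductance, so the guarantee holds for the actual integration scheme
    and the configured inhibitory cell parameters.
    """

    def fires(w: float) -> bool:
        state = NeuronPopulationState.resting(1, p_inh)
        deliver_spikes(state, np.array([w]), 0.0)
        for _ in range(int(math.ceil(2.0 / dt))):
            step_population(state, p_inh, _FROZEN, dt)
            if state.spiked[0]:
                return True
        return False

    lo, hi = 0.0, 1.0
    while not fires(hi):
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("could not find a relaying exc->inh weight")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi * margin


class Network:
    """Simulation handle holding all state; built by :func:`build_network`."""

    def __init__(
        self,
        cfg: NetworkConfig,
        exc_params: NeuronParams,
        inh_params: NeuronParams,
        homeo: HomeostasisParams,
        rule: pl.RuleParams,
        seed: int,
    ):
        self.cfg = cfg
        self.exc_params = exc_params
        self.inh_params = inh_params
        self.homeo = homeo
        self.rule = rule
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.n_presentations = 0
        self.evaluation = False  # when True: theta frozen regardless of homeo.enabled

        self.w = pl.init_weights(cfg.n_input, cfg.n_exc, self.rng, rule.w_max)
        self.traces = pl.TraceState.zeros(cfg.n_input, cfg.n_exc, rule)
        self.exc = NeuronPopulationState.resting(cfg.n_exc, exc_params)
        self.inh = NeuronPopulationState.resting(cfg.n_exc, inh_params)

        if cfg.w_exc_to_inh is None:
            self.w_exc_to_inh = relay_weight(inh_params, cfg.dt, cfg.relay_margin)
        else:
            self.w_exc_to_inh = cfg.w_exc_to_inh
        self.w_inh_to_exc = cfg.w_inh_to_exc

        # one-step synaptic delay buffers (boolean spike masks)
        self._pending_ei = np.zeros(cfg.n_exc, dtype=bool)
        self._pending_ie = np.zeros(cfg.n_exc, dtype=bool)

    # -- structure -----------------------------------------------------

    def inh_to_exc_matrix(self) -> np.ndarray:
        """Dense lateral-inhibition weight matrix: all-to-all minus the diagonal."""
        n = self.cfg.n_exc
        return self.w_inh_to_exc * (1.0 - np.eye(n))

    def synapses(self) -> pl.SynapseMatrix:
        return pl.SynapseMatrix(w=self.w, w_max=self.rule.w_max)

    # -- modes ---------------------------------------------------------

    def set_evaluation_mode(self, on: bool) -> None:
        """Freeze/unfreeze the adaptive threshold (learning is a per-call flag)."""
        self.evaluation = bool(on)

    def normalize_weights(self) -> None:
        # rescale each neuron's incoming sum, then re-impose the hard ceiling
        # (rescaling can push individual weights above w_max)
        pl.normalize_divisive(self.w, self.rule.norm_target)
        pl.clip_weights(self.w, self.rule.w_max)

    # -- simulation ----------------------------------------------------

    def _homeo(self) -> HomeostasisParams:
        return _FROZEN if self.evaluation else self.homeo

    def run_presentation(self, raster: np.ndarray, learning: bool = False) -> SpikeRecord:
        """Advance the network through one stimulus raster.

        ``raster`` is a (n_steps, n_input) boolean array of input spikes at
        resolution ``cfg.dt``.  Plasticity is applied only when ``learning``.
        Returns the excitatory spike counts (and times if configured).
        """
        cfg, rule, tr, w = self.cfg, self.rule, self.traces, self.w
        raster = np.asarray(raster)
        if raster.ndim != 2 or raster.shape[1] != cfg.n_input:
            raise ValueError(
                f"raster must have {cfg.n_input} columns, got shape {raster.shape}"
            )
        h = self._homeo()
        counts = np.zeros(cfg.n_exc, dtype=np.int64)
        times: list[tuple[int, float]] | None = [] if cfg.record_times else None

        f_pre = math.exp(-cfg.dt / tr.tau_pre)
        f_post = math.exp(-cfg.dt / tr.tau_post)
        f_slow = math.exp(-cfg.dt / tr.tau_post_slow)
        track_post = learning and rule.uses_post_trace
        is_prepost = rule.rule_id == "prepost"
        is_triplet = rule.rule_id == "triplet"
        is_powerlaw = rule.rule_id == "powerlaw"

        # pre-split input spike indices by step (cheaper than per-step nonzero)
        n_steps = raster.shape[0]
        step_of_spike, neuron_of_spike = np.nonzero(raster)
        per_step = np.split(
            neuron_of_spike, np.searchsorted(step_of_spike, np.arange(1, n_steps))
        )

        for t in range(n_steps):
            pre_idx = per_step[t]
            tr.x_pre *= f_pre
            if track_post:
                tr.x_post *= f_post
                if is_triplet:
                    tr.x_post_slow *= f_slow
            if pre_idx.size:
                if learning:
                    if is_prepost:
                        rows = w[pre_idx]
                        rows += pl.dw_prepost_pre(tr.x_post, rows, rule)
                        np.clip(rows, 0.0, rule.w_max, out=rows)
                        w[pre_idx] = rows
                    elif is_triplet:
                        rows = w[pre_idx]
                        rows += pl.dw_triplet("pre", tr, rule)
                        np.clip(rows, 0.0, rule.w_max, out=rows)
                        w[pre_idx] = rows
                tr.x_pre[pre_idx] += 1.0
                self.exc.g_e += w[pre_idx].sum(axis=0)

            # delayed lateral inhibition from last step's inhibitory spikes
            n_inh_spikes = int(self._pending_ie.sum())
            if n_inh_spikes:
                self.exc.g_i += self.w_inh_to_exc * n_inh_spikes
                self.exc.g_i[self._pending_ie] -= self.w_inh_to_exc  # self-exemption

            step_population(self.exc, self.exc_params, h, cfg.dt)
            exc_sp = np.flatnonzero(self.exc.spiked)
            if exc_sp.size:
                counts[exc_sp] += 1
                if times is not None:
                    t_ms = (t + 1) * cfg.dt
                    times.extend((int(j), t_ms) for j in exc_sp)
                if learning:
                    cols = w[:, exc_sp]
                    if is_powerlaw:
                        cols += pl.dw_powerlaw(tr.x_pre[:, None], cols, rule)
                    elif rule.rule_id == "expdep":
                        cols += pl.dw_expdep(tr.x_pre[:, None], cols, rule)
                    elif is_prepost:
                        cols += pl.dw_prepost_post(tr.x_pre[:, None], cols, rule)
                    else:
                        for k, j in enumerate(exc_sp):
                            cols[:, k] += pl.dw_triplet("post", tr, rule, post_neuron=j)
                    np.clip(cols, 0.0, rule.w_max, out=cols)
                    w[:, exc_sp] = cols
                if track_post:
                    tr.x_post[exc_sp] += 1.0
                    if is_triplet:
                        tr.x_post_slow[exc_sp] += 1.0

            # delayed exc -> paired-inh relay
            if self._pending_ei.any():
                self.inh.g_e[self._pending_ei] += self.w_exc_to_inh
            step_population(self.inh, self.inh_params, _FROZEN, cfg.dt)

            self._pending_ei = self.exc.spiked
            self._pending_ie = self.inh.spiked

        self.n_presentations += 1
        return SpikeRecord(counts=counts, times=times)

    def run_rest(self) -> "Network":
        """Simulate the input-free rest phase between presentations.

        All fast variables (voltages, conductances, traces, delay buffers)
        decay toward rest; the adaptive threshold is exempt from any reset
        and only decays by its own slow time constant.
        """
        cfg = self.cfg
        h = self._homeo()
        n_steps = int(round(cfg.rest_ms / cfg.dt))
        f_pre = math.exp(-cfg.dt / self.traces.tau_pre)
        f_post = math.exp(-cfg.dt / self.traces.tau_post)
        f_slow = math.exp(-cfg.dt / self.traces.tau_post_slow)
        done = 0
        while done < n_steps:
            if done % 20 == 0 and self._quiescent():
                break
            self.traces.x_pre *= f_pre
            self.traces.x_post *= f_post
            self.traces.x_post_slow *= f_slow
            n_inh_spikes = int(self._pending_ie.sum())
            if n_inh_spikes:
                self.exc.g_i += self.w_inh_to_exc * n_inh_spikes
                self.exc.g_i[self._pending_ie] -= self.w_inh_to_exc
            step_population(self.exc, self.exc_params, h, cfg.dt)
            if self._pending_ei.any():
                self.inh.g_e[self._pending_ei] += self.w_exc_to_inh
            step_population(self.inh, self.inh_params, _FROZEN, cfg.dt)
            self._pending_ei = self.exc.spiked
            self._pending_ie = self.inh.spiked
            done += 1
        remaining = n_steps - done
        if remaining > 0:
            self._decay_closed_form(remaining * cfg.dt, h)
        return self

    def _quiescent(self) -> bool:
        """No pending spikes, no refractory clocks, negligible conductance.

        In this regime every remaining rest variable has an exact closed-form
        decay and no further spike can occur (voltages relax monotonically
        toward rest, below threshold), so the rest phase can be completed
        analytically without changing the result beyond float rounding.
        """
        if self._pending_ei.any() or self._pending_ie.any():
            return False
        for pop in (self.exc, self.inh):
            if pop.refrac_remaining.max(initial=0.0) > 0.0:
                return False
            if pop.g_e.sum() + pop.g_i.sum() > 1e-13:
                return False
        return True

    def _decay_closed_form(self, t_ms: float, h: HomeostasisParams) -> None:
        for pop, p in ((self.exc, self.exc_params), (self.inh, self.inh_params)):
            pop.v = p.e_rest + (pop.v - p.e_rest) * math.exp(-t_ms / p.tau_m)
            pop.g_e *= math.exp(-t_ms / p.tau_ge)
            pop.g_i *= math.exp(-t_ms / p.tau_gi)
            pop.spiked = np.zeros(len(pop), dtype=bool)
        if h.enabled:
            self.exc.theta *= math.exp(-t_ms / h.tau_theta)
        self.traces.x_pre *= math.exp(-t_ms / self.traces.tau_pre)
        self.traces.x_post *= math.exp(-t_ms / self.traces.tau_post)
        self.traces.x_post_slow *= math.exp(-t_ms / self.traces.tau_post_slow)


def build_network(
    cfg: NetworkConfig,
    seed: int,
    exc_params: NeuronParams | None = None,
    inh_params: NeuronParams | None = None,
    homeo: HomeostasisParams | None = None,
    rule: pl.RuleParams | None = None,
) -> Network:
    """Realize the two-layer architecture with seeded random initial weights.

    Connectivity: input->exc all-to-all plastic; exc->inh one-to-one fixed
    (weight computed at build time to guarantee spike relay unless given);
    inh->exc dense fixed with a zero diagonal.
    """
    from .config import inhibitory_reference  # local import avoids a cycle

    if exc_params is None:
        exc_params = NeuronParams()
    if inh_params is None:
        inh_params = inhibitory_reference()
    if homeo is None:
        homeo = HomeostasisParams()
    if rule is None:
        rule = pl.default_rule_params("powerlaw")
    return Network(cfg, exc_params, inh_params, homeo, rule, seed)


def train_network(
    net: Network,
    images,
    rng: np.random.Generator,
    log_path=None,
    epoch_summary_path=None,
):
    """Run the unsupervised training protocol over a sequence of images.

    Per image: (optional) divisive weight normalization, presentation with
    the minimum-response retry loop and plasticity on, then the rest phase.
    No labels are used.  Returns the list of per-presentation SpikeRecords
    (training responses, usable for trailing-block accuracy curves).
    Writes one log line per presentation when ``log_path`` is given, and a
    JSON summary when ``epoch_summary_path`` is given.
    """
    net.set_evaluation_mode(False)
    records = []
    total_retries = 0
    log = open(log_path, "w") if log_path else None
    try:
        for idx, img in enumerate(images):
            if net.cfg.normalize_every_presentation:
                net.normalize_weights()
            record, retries = present_with_retry(net, img, learning=True, rng=rng)
            net.run_rest()
            records.append(record)
            total_retries += retries
            if log is not None:
                log.write(f"{idx}\t{retries}\t{int(record.counts.sum())}\n")
    finally:
        if log is not None:
            log.close()
    if epoch_summary_path:
        summary = {
            "n_presentations": len(records),
            "total_retries": total_retries,
            "mean_exc_spikes": float(np.mean([r.counts.sum() for r in records]))
            if records
            else 0.0,
            "rule_id": net.rule.rule_id,
            "n_exc": net.cfg.n_exc,
            "seed": net.seed,
        }
        with open(epoch_summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
    return records
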