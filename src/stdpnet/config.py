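"""Reference parameter sets, per-size presets, and YAML (de)serialization.

The neuron equations are leak-normalized, so all weights and conductances
are dimensionless multiples of the leak conductance.  Physical conductances
(e.g. a 10 nS lateral-inhibition synapse) map to these units through a
configurable leak-conductance scale; the reference mapping uses 1 nS of
leak per unit divided into the inhibition strength actually used, so the
lateral weight is stored directly in leak units.  Every value here is a
documented choice, externally settable through config files — none is a
hard-coded constant of the simulator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .dynamics import HomeostasisParams, NeuronParams
from .plasticity import RuleParams, default_rule_params
from .network import NetworkConfig

__all__ = [
    "RunConfig",
    "excitatory_reference",
    "inhibitory_reference",
    "reference_config",
    "preset",
    "save_config",
    "load_config",
]


def excitatory_reference() -> NeuronParams:
    """Excitatory cell: long 100 ms membrane constant so the neuron averages
    over ~6 input spikes at the 63.75 Hz peak rate instead of ~1."""
    return NeuronParams(
        e_rest=-65.0, e_exc=0.0, e_inh=-100.0, tau_m=100.0,
        v_thresh=-52.0, v_reset=-65.0, t_refrac=5.0, tau_ge=1.0, tau_gi=2.0,
    )


def inhibitory_reference() -> NeuronParams:
    """Inhibitory cell: fast (10 ms) membrane, fires reliably when relayed."""
    return NeuronParams(
        e_rest=-60.0, e_exc=0.0, e_inh=-85.0, tau_m=10.0,
        v_thresh=-40.0, v_reset=-45.0, t_refrac=2.0, tau_ge=1.0, tau_gi=2.0,
    )


@dataclass
class RunConfig:
    """Bundle of every parameter group needed to build and run a network."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    exc_neuron: NeuronParams = field(default_factory=excitatory_reference)
    inh_neuron: NeuronParams = field(default_factory=inhibitory_reference)
    homeostasis: HomeostasisParams = field(default_factory=HomeostasisParams)
    rule: RuleParams = field(default_factory=RuleParams)


def reference_config(n_exc: int = 100, rule_id: str = "powerlaw", **rule_overrides) -> RunConfig:
    """The named reference configuration at a given network size."""
    return RunConfig(
        network=NetworkConfig(n_exc=n_exc),
        rule=default_rule_params(rule_id, **rule_overrides),
    )


# Lateral inhibition and the adaptive-threshold schedule must be adapted with
# network size to keep the per-presentation response rate roughly constant:
# fewer neurons means each neuron wins more often (faster theta accumulation,
# hence a shorter homeostatic memory so theta equilibrates instead of
# drifting into the conductance-saturation ceiling) and hears fewer
# competitors (weaker total lateral inhibition per spike).
_SIZE_PRESETS = {
    # n_exc threshold: (w_inh_to_exc, theta_plus, tau_theta)
    50: (8.0, 0.05, 1e6),    # small networks (tests, synthetic fixtures)
    200: (17.0, 0.05, 1e7),  # the 100-neuron reference scale
    1000: (22.0, 0.02, 1e7), # 400-neuron scale
}


def preset(n_exc: int, rule_id: str = "powerlaw", **overrides) -> RunConfig:
    """Reference configuration with size-adapted inhibition and homeostasis."""
    for bound in sorted(_SIZE_PRESETS):
        if n_exc <= bound:
            w_ie, theta_plus, tau_theta = _SIZE_PRESETS[bound]
            break
    else:
        w_ie, theta_plus, tau_theta = _SIZE_PRESETS[max(_SIZE_PRESETS)]
    cfg = RunConfig(
        network=NetworkConfig(n_exc=n_exc, w_inh_to_exc=w_ie),
        homeostasis=HomeostasisParams(theta_plus=theta_plus, tau_theta=tau_theta),
        rule=default_rule_params(rule_id),
    )
    for key, val in overrides.items():
        section, _, name = key.partition(".")
        group = getattr(cfg, section)
        setattr(cfg, section, dataclasses.replace(group, **{name: val}))
    return cfg


_SECTIONS = {
    "network": NetworkConfig,
    "exc_neuron": NeuronParams,
    "inh_neuron": NeuronParams,
    "homeostasis": HomeostasisParams,
    "rule": RuleParams,
}


def save_config(cfg: RunConfig, path) -> None:
    """Serialize to YAML: one section per parameter group, keys = field names.

    Units: voltages mV, times ms, rates Hz, weights/conductances leak units.
    """
    payload = {
        section: dataclasses.asdict(getattr(cfg, section)) for section in _SECTIONS
    }
    with open(path, "w") as fh:
        fh.write("# stdpnet run configuration\n")
        fh.write("# units: voltages mV, times ms, rates Hz, weights in leak-conductance units\n")
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in payload:
            kwargs[section] = cls(**payload[section])
    return RunConfig(**kwargs)
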