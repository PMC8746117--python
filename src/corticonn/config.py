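"""YAML run configuration -> NetworkSpec.

A config file may override any simulation parameter, grouped by section::

    duration: 10.0      # seconds
    dt: 0.1             # ms
    seed: 7
    population: {N_E: 1600, N_I: 400, p_intra: 0.10, background_rate: 7300.0}
    long_range: {p_inter: 0.05, mu_E: 50.0, mu_I: 25.0, conduction_speed: 3.5}
    neurons:   {g_Na: 12.5}
    synapses:
      tau_exc: 2.0
      weight_table: {EE: [2.5, 1.0]}

Unspecified values keep the model defaults.
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .connectome import DistanceMatrix, FLNMatrix
from .network import (
    LongRangeSpec,
    NetworkSpec,
    NeuronParameters,
    PopulationSpec,
    SynapseParams,
)

__all__ = ["load_config", "spec_from_config"]

_SECTIONS = {
    "population": PopulationSpec,
    "synapses": SynapseParams,
    "neurons": NeuronParameters,
    "long_range": LongRangeSpec,
}


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def spec_from_config(
    fln: FLNMatrix, distances: DistanceMatrix, cfg: dict, **overrides
) -> NetworkSpec:
    """Build a NetworkSpec from a config mapping; keyword overrides (e.g.
    ``seed=...``) win over the file."""
    kw = {}
    for section, cls in _SECTIONS.items():
        params = dict(cfg.get(section, {}))
        if section == "synapses" and "weight_table" in params:
            base = SynapseParams().weight_table
            base.update({k: tuple(v) for k, v in params["weight_table"].items()})
            params["weight_table"] = base
        kw[section] = cls(**params)
    for key in ("duration", "dt", "seed", "spike_threshold", "refractory_detect"):
        if key in cfg:
            kw[key] = cfg[key]
    spec = NetworkSpec(fln=fln, distances=distances, **kw)
    return replace(spec, **overrides) if overrides else spec
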