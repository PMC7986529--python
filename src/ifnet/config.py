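"""Run-configuration files.

A run can be described by a single YAML (or JSON) mapping whose sections
mirror the parameter containers:

```yaml
seed: 7
sim:        {h: 0.1, theta: 5000.0}
plasticity: {r: 100.0, c: 0.55}
topology:   {p_exc: 0.16666667}
bias:       {total_rate: 1800.0, correlated_fraction: 0.3}
protocol:   {variant: spike_triggered, delay: 10.0}
episodes:   {frequency: 20.0, cycles: 6}     # optional
schedule:
  periods:
    - [preconditioning, 60.0, true, false]
    - [pretest, 40.0, false, false]
    - [conditioning, 100.0, true, true]
    - [posttest, 40.0, false, false]
  test_interval_s: 0.25
```

Unknown keys raise, listing the offending entries.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .params import BiasConfig, EpisodeSpec, PlasticityParams, SimulationParams
from .protocols import ProtocolSpec
from .run import PeriodSpec, RunConfig, ScheduleSpec
from .topology import TopologySpec

__all__ = ["load_config", "config_from_dict"]

_SECTIONS = {
    "sim": SimulationParams,
    "plasticity": PlasticityParams,
    "topology": TopologySpec,
    "bias": BiasConfig,
    "protocol": ProtocolSpec,
    "episodes": EpisodeSpec,
}
_FIELD_NAME = {
    "sim": "sim", "plasticity": "plast", "topology": "topo",
    "bias": "bias", "protocol": "protocol", "episodes": "episodes",
}


def _build(cls, mapping: dict, section: str):
    valid = set(cls.__dataclass_fields__)
    bad = set(mapping) - valid
    if bad:
        raise ValueError(f"unknown keys in section {section!r}: {sorted(bad)}")
    return cls(**mapping)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    kwargs = {}
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    for section, cls in _SECTIONS.items():
        if section in data:
            kwargs[_FIELD_NAME[section]] = _build(cls, data.pop(section), section)
    if "schedule" in data:
        sched = data.pop("schedule")
        periods = tuple(
            PeriodSpec(str(n), float(d), bool(p), bool(c))
            for n, d, p, c in sched.pop("periods", [])
        ) or None
        extra = {k: sched.pop(k) for k in ("test_interval_s", "wtrack_interval_ms")
                 if k in sched}
        if sched:
            raise ValueError(f"unknown keys in section 'schedule': {sorted(sched)}")
        kwargs["schedule"] = (
            ScheduleSpec(periods=periods, **extra) if periods is not None
            else ScheduleSpec(**extra)
        )
    for flag in ("record_spikes", "store_lfp"):
        if flag in data:
            kwargs[flag] = bool(data.pop(flag))
    if data:
        raise ValueError(f"unknown top-level config keys: {sorted(data)}")
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON run-configuration file into a validated RunConfig."""
    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(data)
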