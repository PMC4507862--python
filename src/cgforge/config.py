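"""Run configuration: structured key-value files driving the workflow.

A config file is YAML with four blocks::

    system:                 # what to coarse-grain
      kind: lj_fluid        # fixture kind (or trajectory: path to XYZ)
      n: 60
      rho: 0.45
      temperature: 1.0
      seed: 7
    sampler:                # CG-ensemble sampling per iteration
      n_steps: 100000
      stride: 250
      equilibration: 0.25
      max_disp: 0.35
    method:                 # re | simplex, plus method options
      name: re
      r_cut: 1.8
      dr: 0.1
      chi: 1.0
      tol: 1.0e-4
      max_iter: 10
    output: out/

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]

_SYSTEM_KEYS = {"kind", "n", "rho", "temperature", "seed", "x",
                "bin_width", "r_max", "n_steps", "stride"}
_SAMPLER_KEYS = {"n_steps", "stride", "equilibration", "max_disp"}
_METHOD_KEYS = {"name", "r_cut", "dr", "chi", "tol", "max_iter", "window",
                "w_lambda", "w_u", "seed",
                "pair", "max_steps", "relax_steps", "spread",
                "pressure_weight", "r_lo", "r_hi",
                "sigma", "eps", "w_c", "h", "p", "s"}


@dataclass
class RunConfig:
    """Validated workflow configuration."""

    system: dict
    sampler: dict = field(default_factory=dict)
    method: dict = field(default_factory=dict)
    output: str = "out"

    def __post_init__(self):
        for block, allowed in (("system", _SYSTEM_KEYS),
                               ("sampler", _SAMPLER_KEYS),
                               ("method", _METHOD_KEYS)):
            unknown = set(getattr(self, block)) - allowed
            if unknown:
                raise ValueError(f"unknown {block} option(s): "
                                 f"{sorted(unknown)}")
        name = self.method.get("name", "re")
        if name not in ("re", "simplex"):
            raise ValueError(f"method name must be 're' or 'simplex', "
                             f"got {name!r}")
        self.method.setdefault("name", name)
        self.system.setdefault("kind", "lj_fluid")
        self.system.setdefault("seed", 0)

    @property
    def method_name(self) -> str:
        return self.method["name"]

    @property
    def outdir(self) -> Path:
        return Path(self.output)

    def echo(self) -> str:
        return yaml.safe_dump({"system": self.system, "sampler": self.sampler,
                               "method": self.method, "output": self.output},
                              sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "system" not in raw:
        raise ValueError(f"{path}: config must contain a 'system' block")
    return RunConfig(system=raw.get("system", {}),
                     sampler=raw.get("sampler", {}),
                     method=raw.get("method", {}),
                     output=raw.get("output", "out"))
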