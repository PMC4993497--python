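"""Run configuration: the constants table plus run options, YAML-backed.

A run config has a ``constants`` block mirroring :class:`ModelConstants`
and an ``options`` block for the solver conventions.  Unknown keys are
rejected so typos fail loudly; command-line flags override file values,
and overridden constants are recorded for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional

import yaml

from .errors import BiodynError
from .parameterisation import DEFAULT_CONSTANTS, ModelConstants

__all__ = ["RunConfig", "load_config"]

_OPTION_DEFAULTS = {
    "forcing_convention": "mean",     # pre/post combination for water renewals
    "cf_sampling": "start",           # parasite forcing sampling point
    "weight_dynamics": "static",      # weight ratio handling in Cf
    "parasite_loss": "np_gp",         # parasite loss-rate convention
    "seed": 0,
}


@dataclass
class RunConfig:
    constants: ModelConstants = field(default_factory=ModelConstants)
    options: Dict = field(default_factory=lambda: dict(_OPTION_DEFAULTS))
    overridden: Dict = field(default_factory=dict)

    def override(self, **kw) -> "RunConfig":
        """Apply non-None overrides; records which constants changed."""
        const_fields = {f.name for f in dataclasses.fields(ModelConstants)}
        constants = self.constants
        options = dict(self.options)
        overridden = dict(self.overridden)
        for key, value in kw.items():
            if value is None:
                continue
            if key in const_fields:
                overridden[key] = (getattr(constants, key), value)
                constants = constants.replace(**{key: value})
            elif key in options:
                options[key] = value
            else:
                raise BiodynError(f"unknown configuration key {key!r}")
        return RunConfig(constants=constants, options=options,
                         overridden=overridden)

    def describe(self) -> str:
        lines = ["constants:"]
        for f in dataclasses.fields(ModelConstants):
            mark = "  (overridden)" if f.name in self.overridden else ""
            lines.append(f"  {f.name} = {getattr(self.constants, f.name)}{mark}")
        lines.append("options:")
        for k, v in self.options.items():
            lines.append(f"  {k} = {v}")
        return "\n".join(lines)


def load_config(path: Optional[str] = None) -> RunConfig:
    """Load a YAML run config; missing path gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"constants", "options"}
    if unknown:
        raise BiodynError(f"unknown config sections: {sorted(unknown)}")
    const_fields = {f.name for f in dataclasses.fields(ModelConstants)}
    const_raw = raw.get("constants", {}) or {}
    bad = set(const_raw) - const_fields
    if bad:
        raise BiodynError(f"unknown constants: {sorted(bad)}")
    opt_raw = raw.get("options", {}) or {}
    bad = set(opt_raw) - set(_OPTION_DEFAULTS)
    if bad:
        raise BiodynError(f"unknown options: {sorted(bad)}")
    options = dict(_OPTION_DEFAULTS)
    options.update(opt_raw)
    return RunConfig(constants=DEFAULT_CONSTANTS.replace(**const_raw),
                     options=options)
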