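"""Run configuration: one YAML/JSON document defining the model, the
systems (name, potential, budgets, seeds), and shared defaults."""

from __future__ import annotations

from typing import Optional

import yaml

from .errors import ValidationError
from .model import MilestoningModel
from .potentials import PotentialSpec
from .ranking import SystemSpec

__all__ = ["load_config", "parse_config"]

_DEFAULTS = {
    "replicas": 3,
    "n_steps": 200_000,
    "dt": 1e-3,
    "diffusion": 1.0,
    "seed": 0,
    "pull_speed": 0.05,
    "restraint_stiffness": 100.0,
    "include_bound_cell": True,
}


def parse_config(doc: dict, overrides: Optional[dict] = None
                 ) -> tuple[MilestoningModel, list[SystemSpec]]:
    if not isinstance(doc, dict) or "model" not in doc:
        raise ValidationError("config must be a mapping with a 'model' entry")
    model = MilestoningModel.from_dict(doc["model"])
    defaults = {**_DEFAULTS, **doc.get("defaults", {})}
    if overrides:
        defaults.update({k: v for k, v in overrides.items() if v is not None})
    systems_doc = doc.get("systems", [])
    if not systems_doc:
        raise ValidationError("config defines no systems")
    specs = []
    for entry in systems_doc:
        if "name" not in entry or "potential" not in entry:
            raise ValidationError(
                "every system needs a 'name' and a 'potential'"
            )
        merged = {**defaults, **{k: v for k, v in entry.items()
                                 if k not in ("name", "potential")}}
        specs.append(
            SystemSpec(
                name=str(entry["name"]),
                model=model,
                potential=PotentialSpec.from_dict(entry["potential"]),
                n_replicas=int(merged["replicas"]),
                n_steps_per_cell=int(merged["n_steps"]),
                dt=float(merged["dt"]),
                diffusion_coefficient=float(merged["diffusion"]),
                master_seed=int(merged["seed"]),
                include_bound_cell=bool(merged["include_bound_cell"]),
                pull_speed=float(merged["pull_speed"]),
                restraint_stiffness=float(merged["restraint_stiffness"]),
            )
        )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate system names in config: {names}")
    return model, specs


def load_config(path, overrides: Optional[dict] = None):
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc, overrides=overrides)
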