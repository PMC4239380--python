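"""JSON (de)serialisation of simulation configurations.

A config file mirrors SimulationConfig field-for-field; the dormancy block is
tagged with a ``kind`` of "none", "dormancy" or "late_dormancy". The schema
shipped at ``metasim/schemas/simulation_config.schema.json`` documents the
format.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Union

from .colonization import ColonizationModel
from .engine import PrimaryTumor, SimulationConfig
from .growth import DormancyConfig, DormancyRegime, LateDormancyConfig

__all__ = ["config_to_dict", "config_from_dict", "load_config", "save_config"]


def _dormancy_to_dict(regime: DormancyRegime) -> dict[str, Any]:
    if regime is None:
        return {"kind": "none"}
    if isinstance(regime, DormancyConfig):
        return {"kind": "dormancy", **asdict(regime)}
    if isinstance(regime, LateDormancyConfig):
        return {"kind": "late_dormancy", **asdict(regime)}
    raise TypeError(f"unknown dormancy regime {regime!r}")


def _dormancy_from_dict(d: dict[str, Any]) -> DormancyRegime:
    kind = d.get("kind", "none")
    params = {k: v for k, v in d.items() if k != "kind"}
    if kind == "none":
        return None
    if kind == "dormancy":
        return DormancyConfig(**params)
    if kind == "late_dormancy":
        return LateDormancyConfig(**params)
    raise ValueError(f"unknown dormancy kind {kind!r}")


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    return {
        "primary": asdict(config.primary),
        "colonization": asdict(config.colonization),
        "duration": config.duration,
        "kill_probability": config.kill_probability,
        "metastasis_growth_factor": config.metastasis_growth_factor,
        "dormancy": _dormancy_to_dict(config.dormancy),
        "snapshot_interval": config.snapshot_interval,
        "replicates": config.replicates,
        "seed": config.seed,
    }


def config_from_dict(d: dict[str, Any]) -> SimulationConfig:
    return SimulationConfig(
        primary=PrimaryTumor(**d["primary"]),
        colonization=ColonizationModel(**d["colonization"]),
        duration=d["duration"],
        kill_probability=d.get("kill_probability", 0.0),
        metastasis_growth_factor=d.get("metastasis_growth_factor", 1.0),
        dormancy=_dormancy_from_dict(d.get("dormancy", {"kind": "none"})),
        snapshot_interval=d.get("snapshot_interval", 1.0),
        replicates=d.get("replicates", 100),
        seed=d.get("seed", 0),
    )


def load_config(path: Union[str, Path]) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))


def save_config(config: SimulationConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2)
        fh.write("\n")
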