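"""Structured config files (YAML/JSON) for flume, life stages, turbine and
Monte Carlo specifications, plus the JSON run manifest."""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from pshpassage import __version__
from pshpassage.bladestrike import StochasticSpec, TurbineConfig
from pshpassage.shear import FlumeConfig, LifeStage, LifeStageSpec


def load_mapping(path: str | Path) -> dict:
    """Read a YAML or JSON mapping by extension (YAML parses JSON too)."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def dump_mapping(data: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(data, fh, sort_keys=True)


def flume_from_config(cfg: dict) -> FlumeConfig:
    return FlumeConfig(
        gravitational_acceleration=cfg.get("gravitational_acceleration", 9.81),
        gauge_range_psi=tuple(cfg.get("gauge_range_psi", (0.0, 45.0))),
        nozzle_inlet_diameter=cfg.get("nozzle_inlet_diameter", 0.15),
        nozzle_outlet_diameter=cfg.get("nozzle_outlet_diameter", 0.05),
    )


def life_stage_from_config(cfg: dict) -> LifeStageSpec:
    return LifeStageSpec(
        name=LifeStage(cfg["name"]),
        characteristic_width_y=cfg["characteristic_width_y"],
        length_mean=cfg["length_mean"],
        length_sd=cfg["length_sd"],
        length_min=cfg["length_min"],
        length_max=cfg["length_max"],
        n_per_replicate=cfg["n_per_replicate"],
    )


def life_stage_to_config(spec: LifeStageSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["name"] = spec.name.value
    return d


def turbine_from_config(cfg: dict) -> TurbineConfig:
    return TurbineConfig(
        n_blades=cfg["n_blades"],
        rotation_speed_rpm=cfg["rotation_speed_rpm"],
        runner_inlet_diameter=cfg["runner_inlet_diameter"],
        runner_inlet_height=cfg["runner_inlet_height"],
        operating_table=tuple(
            (row[0], row[1]) for row in cfg["operating_table"]
        ),
    )


def turbine_to_config(turbine: TurbineConfig) -> dict:
    return {
        "n_blades": turbine.n_blades,
        "rotation_speed_rpm": turbine.rotation_speed_rpm,
        "runner_inlet_diameter": turbine.runner_inlet_diameter,
        "runner_inlet_height": turbine.runner_inlet_height,
        "operating_table": [list(row) for row in turbine.operating_table],
    }


def stochastic_spec_from_config(cfg: dict, seed: int | None = None) -> StochasticSpec:
    return StochasticSpec(
        seed=seed if seed is not None else cfg["seed"],
        n_realizations=cfg.get("n_realizations", 10_000),
        gate_angle_min=cfg.get("gate_angle_min"),
        gate_angle_max=cfg.get("gate_angle_max"),
        orientation_min=cfg.get("orientation_min", 0.0),
        orientation_max=cfg.get("orientation_max", 90.0),
        mutilation_ratio=cfg.get("mutilation_ratio", 1.0),
    )


@dataclass
class RunManifest:
    """Provenance sidecar for a command run: inputs, seed, outputs, version."""

    command: str
    config_paths: list[str]
    seed: int | None
    output_paths: list[str]
    package_version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        dump_mapping(dataclasses.asdict(self), Path(path))


def write_manifest(
    command: str,
    out_dir: Path,
    config_paths: list[str],
    seed: int | None,
    output_paths: list[Path],
) -> Path:
    manifest = RunManifest(
        command=command,
        config_paths=[str(p) for p in config_paths],
        seed=seed,
        output_paths=[str(p) for p in output_paths],
    )
    path = out_dir / f"{command}_manifest.json"
    manifest.write(path)
    return path
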