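"""YAML config round-tripping for geometry, simulation and run configs."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .geometry import ArrayGeometry, ToleranceSpec, WellDimensions
from .simulate import ROX, ChannelLevels, IlluminationField, SimulationConfig


def _check_keys(d: dict, allowed: set[str], what: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown {what} keys: {sorted(unknown)}")


def geometry_from_dict(d: dict[str, Any]) -> ArrayGeometry:
    _check_keys(d, {"well_x_um", "well_y_um", "well_z_um", "rows", "cols",
                    "pitch_x_um", "pitch_y_um"}, "geometry")
    try:
        wells = WellDimensions(float(d.get("well_x_um", 65.0)),
                               float(d.get("well_y_um", 82.0)),
                               float(d.get("well_z_um", 97.0)))
        return ArrayGeometry(wells, int(d.get("rows", 100)), int(d.get("cols", 200)),
                             float(d.get("pitch_x_um", 91.0)),
                             float(d.get("pitch_y_um", 107.0)))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad geometry config: {exc}") from exc


def geometry_to_dict(g: ArrayGeometry) -> dict[str, Any]:
    return {"well_x_um": g.wells.x, "well_y_um": g.wells.y, "well_z_um": g.wells.z,
            "rows": g.rows, "cols": g.cols,
            "pitch_x_um": g.pitch_x, "pitch_y_um": g.pitch_y}


def tolerances_from_dict(d: dict[str, Any]) -> ToleranceSpec:
    _check_keys(d, {"planar_um", "height_um"}, "tolerance")
    return ToleranceSpec(float(d.get("planar_um", 0.1)),
                         float(d.get("height_um", 1.0)))


def simulation_config_from_dict(d: dict[str, Any]) -> SimulationConfig:
    _check_keys(d, {"seed", "geometry", "fill_failure_rate", "pixel_pitch_um",
                    "image_bit_depth", "background", "margin_px", "grid_offset",
                    "channels", "rox", "illumination"}, "simulation")
    geometry = geometry_from_dict(d.get("geometry", {}) or {})
    concentrations: dict[str, float] = {}
    levels: dict[str, ChannelLevels] = {}
    default = SimulationConfig()
    for ch, spec in (d.get("channels") or {"FAM": {}, "HEX": {}}).items():
        spec = spec or {}
        _check_keys(spec, {"concentration", "negative_mean", "positive_mean",
                           "noise_sd"}, f"channel {ch}")
        base = default.levels.get(ch, ChannelLevels(3000.0, 18000.0, 200.0))
        concentrations[ch] = float(spec.get("concentration", 0.0))
        levels[ch] = ChannelLevels(
            float(spec.get("negative_mean", base.negative_mean)),
            float(spec.get("positive_mean", base.positive_mean)),
            float(spec.get("noise_sd", base.noise_sd)))
    rox = d.get("rox") or {}
    _check_keys(rox, {"positive_mean", "noise_sd"}, "rox")
    rox_base = default.levels[ROX]
    levels[ROX] = ChannelLevels(
        float(d.get("background", default.background)),
        float(rox.get("positive_mean", rox_base.positive_mean)),
        float(rox.get("noise_sd", rox_base.noise_sd)))
    illum = d.get("illumination") or {}
    _check_keys(illum, {"kind", "amplitude"}, "illumination")
    offset = d.get("grid_offset", (0.0, 0.0))
    try:
        return SimulationConfig(
            seed=int(d.get("seed", 0)),
            geometry=geometry,
            channel_concentrations=concentrations,
            fill_failure_rate=float(d.get("fill_failure_rate", 0.02)),
            pixel_pitch=float(d.get("pixel_pitch_um", 10.0)),
            image_bit_depth=int(d.get("image_bit_depth", 16)),
            background=float(d.get("background", default.background)),
            levels=levels,
            illumination=IlluminationField(
                illum.get("kind", default.illumination.kind),
                float(illum.get("amplitude", default.illumination.amplitude))),
            grid_offset=(float(offset[0]), float(offset[1])),
            margin_px=int(d.get("margin_px", 20)))
    except (TypeError, ValueError, IndexError) as exc:
        raise ConfigError(f"bad simulation config: {exc}") from exc


def simulation_config_to_dict(c: SimulationConfig) -> dict[str, Any]:
    channels = {}
    for ch in c.probe_channels:
        lv = c.levels[ch]
        channels[ch] = {"concentration": c.channel_concentrations[ch],
                        "negative_mean": lv.negative_mean,
                        "positive_mean": lv.positive_mean,
                        "noise_sd": lv.noise_sd}
    rox = c.levels[ROX]
    return {"seed": c.seed,
            "geometry": geometry_to_dict(c.geometry),
            "fill_failure_rate": c.fill_failure_rate,
            "pixel_pitch_um": c.pixel_pitch,
            "image_bit_depth": c.image_bit_depth,
            "background": c.background,
            "margin_px": c.margin_px,
            "grid_offset": list(c.grid_offset),
            "channels": channels,
            "rox": {"positive_mean": rox.positive_mean, "noise_sd": rox.noise_sd},
            "illumination": {"kind": c.illumination.kind,
                             "amplitude": c.illumination.amplitude}}


def load_yaml(path: str | Path) -> dict[str, Any]:
    try:
        with open(path) as fh:
            d = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return d


def load_simulation_config(path: str | Path) -> SimulationConfig:
    return simulation_config_from_dict(load_yaml(path))


def save_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(simulation_config_to_dict(config), fh, sort_keys=True)


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of the canonicalized config, for provenance logs."""
    text = yaml.safe_dump(simulation_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
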