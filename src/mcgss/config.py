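"""Experiment configuration: named profiles plus YAML/JSON loading.

Profiles
--------
``onelayer_full``
    The full reference setup: 26x37x1 sheet of 2.5 mm voxels (962 voxels,
    2886 states), 1 s at 2000 Hz, 4x4x3 tri-axial sensors (144 channels),
    amplitude factor 70, 40 fT/sqrt(Hz) noise, eta=200, gamma=1, 2000 epochs.
``onelayer_reduced``
    A geometrically similar sheet at reduced problem size (14x20 voxels,
    1 kHz, 3x3x2 sensors) for desk-scale end-to-end runs of the nested
    optimization; same physics, same velocities, same noise model.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .experiment import ExperimentConfig
from .geometry import DEFAULT_VELOCITIES, SheetLayout, VoxelType
from .kalman import KalmanConfig
from .propagation import APTemplateParams
from .refinement import RefinementConfig


class ConfigError(ValueError):
    pass


REDUCED_LAYOUT = SheetLayout(
    atria_min_row=14,
    sa_site=(2, 17),
    av_site=(7, 13),
    his_column_x=7,
    his_rows=(2, 12),
    his_branch_row=2,
    his_branch_cols=(2, 11),
    patch_cols=(2, 4),
    patch_rows=(6, 9),
)


def get_profile(name: str) -> ExperimentConfig:
    if name == "onelayer_full":
        return ExperimentConfig()
    if name == "onelayer_reduced":
        # all lengths scale with the sheet (factor ~0.54) so the patch
        # subtends the same angle at the array as in the full-size study;
        # without this the reduced patch is below the spatial resolution
        return ExperimentConfig(
            dims=(14, 20, 1),
            layout=REDUCED_LAYOUT,
            fs=1000.0,
            sensor_counts=(3, 3, 2),
            sensor_extent=(135.0, 135.0, 54.0),
            sensor_height=110.0,
            kalman=KalmanConfig(
                q_diag=1e-4, r_diag=(40e-15 * np.sqrt(500.0)) ** 2, p0_diag=1e-2
            ),
            refinement=RefinementConfig(
                eta=100.0, gamma=1.0, epochs=150, input="open_loop"
            ),
        )
    raise ConfigError(f"unknown profile {name!r}")


_SUBSECTIONS = {
    "layout": SheetLayout,
    "control": APTemplateParams,
    "kalman": KalmanConfig,
    "refinement": RefinementConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {section}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def config_from_dict(data: dict) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig` from a plain dict.

    Unknown keys are rejected with a message listing them.  A ``profile`` key
    selects the base profile; remaining keys override its fields.
    """
    data = dict(data)
    base = get_profile(data.pop("profile", "onelayer_full"))
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    updates = {}
    for key, value in data.items():
        if key in _SUBSECTIONS and isinstance(value, dict):
            updates[key] = _build_section(_SUBSECTIONS[key], value, key)
        elif key == "velocities" and isinstance(value, dict):
            table = dict(DEFAULT_VELOCITIES)
            for tname, v in value.items():
                try:
                    table[VoxelType[tname.upper()]] = float(v)
                except KeyError:
                    raise ConfigError(f"unknown voxel type in velocities: {tname!r}") from None
            updates[key] = table
        elif isinstance(value, list):
            updates[key] = tuple(value)
        else:
            updates[key] = value
    return dataclasses.replace(base, **updates)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML (or JSON) experiment configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    return config_from_dict(data)


def config_to_dict(config: ExperimentConfig) -> dict:
    """Plain-JSON representation (echoed into run containers)."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {
                (k.name if isinstance(k, VoxelType) else k): convert(v) for k, v in obj.items()
            }
        if isinstance(obj, (frozenset, set)):
            return sorted(
                [a.name if isinstance(a, VoxelType) else a for a in pair] for pair in obj
            )
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return convert(config)


def config_to_json(config: ExperimentConfig) -> str:
    return json.dumps(config_to_dict(config), indent=2)
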