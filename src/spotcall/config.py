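"""Parameter-file loading (TOML or YAML) for the CLI.

A config file carries up to three sections, ``segmentation``, ``marker``
and ``call``; every key is optional and falls back to the documented
default of the corresponding dataclass.  Unknown keys are rejected so typos
do not silently revert a parameter to its default.
"""

from __future__ import annotations

import dataclasses
import os
import tomllib

import yaml

from .calling import CallParams
from .marker import MarkerParams
from .segmentation import SegmentationParams

__all__ = ["PipelineConfig", "load_config"]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    segmentation: SegmentationParams
    marker: MarkerParams
    call: CallParams

    def as_dict(self) -> dict:
        return {
            "segmentation": dataclasses.asdict(self.segmentation),
            "marker": dataclasses.asdict(self.marker),
            "call": dataclasses.asdict(self.call),
        }


def _build(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown keys in [{name}] config section: {sorted(unknown)}")
    coerced = dict(section)
    for key in ("rgb_min", "rgb_max"):
        if key in coerced:
            coerced[key] = tuple(coerced[key])
    return cls(**coerced)


def load_config(path: str | os.PathLike | None) -> PipelineConfig:
    """Load a TOML/YAML parameter file; ``None`` yields all defaults."""
    if path is None:
        data = {}
    else:
        path = os.fspath(path)
        if path.endswith(".toml"):
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    unknown = set(data) - {"segmentation", "marker", "call"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return PipelineConfig(
        segmentation=_build(SegmentationParams, data.get("segmentation", {}), "segmentation"),
        marker=_build(MarkerParams, data.get("marker", {}), "marker"),
        call=_build(CallParams, data.get("call", {}), "call"),
    )
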