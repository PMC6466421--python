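"""YAML/JSON run configuration mapped onto the module dataclasses.

One config document holds optional blocks ``geometry``, ``acquisition``,
``population``, ``noise``, ``pipeline`` and ``optics``; missing blocks
and missing keys fall back to the dataclass defaults, and unknown keys
are rejected with the offending field named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .geometry import AcquisitionPlan, ChannelSpec
from .imgproc import PipelineParams
from .photometry import OpticalTrain
from .synthgen import NoiseSpec, PopulationSpec

__all__ = ["RunConfig", "load_config", "default_config_dict", "dump_default_config"]

_BLOCKS = {
    "geometry": ChannelSpec,
    "acquisition": AcquisitionPlan,
    "population": PopulationSpec,
    "noise": NoiseSpec,
    "pipeline": PipelineParams,
    "optics": OpticalTrain,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a simulate/count run."""

    channel: ChannelSpec
    plan: AcquisitionPlan
    population: PopulationSpec
    noise: NoiseSpec
    pipeline: PipelineParams | None  # None -> rescale defaults to the plan
    optics: OpticalTrain
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "geometry": dataclasses.asdict(self.channel),
            "acquisition": dataclasses.asdict(self.plan),
            "population": dataclasses.asdict(self.population),
            "noise": dataclasses.asdict(self.noise),
            "optics": dataclasses.asdict(self.optics),
        }
        if self.pipeline is not None:
            d["pipeline"] = dataclasses.asdict(self.pipeline)
        if self.seed is not None:
            d["seed"] = self.seed
        return d


def _build(cls, block_name: str, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config block {block_name!r}; "
            f"valid keys: {sorted(valid)}"
        )
    if cls is OpticalTrain and "stage_efficiencies" in data:
        data = {**data, "stage_efficiencies": tuple(data["stage_efficiencies"])}
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config block {block_name!r}: {exc}") from exc


def parse_config_dict(doc: dict | None) -> RunConfig:
    doc = dict(doc or {})
    seed = doc.pop("seed", None)
    unknown = set(doc) - set(_BLOCKS)
    if unknown:
        raise ValueError(
            f"unknown config block(s) {sorted(unknown)}; valid: {sorted(_BLOCKS)}"
        )
    built = {
        name: _build(cls, name, doc.get(name, {}) or {})
        for name, cls in _BLOCKS.items()
        if name != "pipeline"
    }
    pipeline = (
        _build(PipelineParams, "pipeline", doc["pipeline"])
        if "pipeline" in doc and doc["pipeline"]
        else None
    )
    if built["optics"] is None:  # pragma: no cover - optics block always builds
        raise AssertionError
    return RunConfig(
        channel=built["geometry"],
        plan=built["acquisition"],
        population=built["population"],
        noise=built["noise"],
        pipeline=pipeline,
        optics=built["optics"],
        seed=seed,
    )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) config file.

    ``None`` yields the all-defaults configuration.
    """
    if path is None:
        return parse_config_dict({})
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
    return parse_config_dict(doc)


def default_config_dict() -> dict:
    """All-defaults configuration as a plain dict (for --print-config)."""
    cfg = parse_config_dict({})
    d = cfg.to_dict()
    d["pipeline"] = dataclasses.asdict(PipelineParams())
    return d


def dump_default_config() -> str:
    return yaml.safe_dump(default_config_dict(), sort_keys=False)
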