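"""Run configuration: one structured YAML document drives a whole run.

A run is reproducible from the RunConfig alone — every random draw is seeded
from ``seed`` (the simulator derives per-library child seeds from it), and
all outputs are plain text written deterministically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .benchmark import BenchmarkConfig, GuidelineTable
from .calling import CallerConfig
from .classify import ClassTaxonomy
from .simulate import SimConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_replicates: int = 2
    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    taxonomy: ClassTaxonomy = field(default_factory=ClassTaxonomy)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    guideline: GuidelineTable = field(default_factory=GuidelineTable)

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed, sim=dataclasses.replace(self.sim, seed=seed)
        )


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, float) and obj == float("inf"):
        return ".inf"
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def _build(cls, data: Mapping[str, Any] | None):
    if data is None:
        return cls()
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} field {k!r}")
        if isinstance(v, list):
            v = _detuple(v)
        if v == ".inf":
            v = float("inf")
        kwargs[k] = v
    return cls(**kwargs)


def _detuple(v: Any) -> Any:
    if isinstance(v, list):
        return tuple(_detuple(x) for x in v)
    if v == ".inf":
        return float("inf")
    return v


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; missing sections take their defaults.

    Raises
    ------
    ValueError
        On unknown keys (schema violation).
    """
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    known = {"seed", "n_replicates", "sim", "caller", "taxonomy", "benchmark", "guideline"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return RunConfig(
        seed=int(data.get("seed", 0)),
        n_replicates=int(data.get("n_replicates", 2)),
        sim=_build(SimConfig, data.get("sim")),
        caller=_build(CallerConfig, data.get("caller")),
        taxonomy=_build(ClassTaxonomy, data.get("taxonomy")),
        benchmark=_build(BenchmarkConfig, data.get("benchmark")),
        guideline=_build(GuidelineTable, data.get("guideline")),
    )
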