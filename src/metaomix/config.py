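"""YAML run configuration: schema, presets, validation.

A run config names either a module preset (1-6, mirroring the classic
multi-omics combinations: 1 = amplicon-only database build, 2 = AS+MP,
3-5 = shotgun-layer combinations, 6 = all four layers) or an explicit
stage list, plus per-stage parameters and input paths. Validation
collects *every* violation before raising, so a user fixes a config in
one pass.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import MetaomixError

__all__ = ["ConfigError", "RunConfig", "validate_config", "PRESETS", "STAGES"]

STAGES = ("profile", "builddb", "peptides", "da", "pathway", "ordination")

#: preset number -> ordered stage list
PRESETS = {
    1: ("profile", "builddb"),
    2: ("profile", "builddb", "peptides", "da", "ordination"),
    3: ("da", "pathway", "ordination"),
    4: ("da", "pathway", "ordination"),
    5: ("da", "pathway", "ordination"),
    6: ("profile", "builddb", "peptides", "da", "pathway", "ordination"),
}

#: stage -> input keys it requires
_STAGE_INPUTS = {
    "profile": ("asv", "taxonomy"),
    "builddb": ("asv", "taxonomy", "proteomes"),
    "peptides": ("psms",),
    "da": ("metadata",),
    "pathway": ("metadata", "pathway"),
    "ordination": ("metadata",),
}

#: presets 3-5 carry no amplicon inputs; they need explicit layer matrices
_PRESET_EXTRA_INPUTS = {
    2: ("metadata", "psms"),
    3: ("layers", "annotations"),
    4: ("layers", "annotations"),
    5: ("layers", "annotations"),
    6: ("layers", "annotations"),
}

_KNOWN_TOP = {"module", "stages", "seed", "out_dir", "inputs", "params"}
_KNOWN_INPUTS = {
    "asv", "asv_taxa", "taxonomy", "metadata", "proteomes", "host",
    "psms", "layers", "annotations", "pathway",
}
_KNOWN_PARAMS = {
    "taxa_level", "top_n", "host", "phenotype", "covariates",
    "normalization", "transform", "groups", "min_prevalence",
    "pseudocount", "combine", "top_k",
}


class ConfigError(MetaomixError):
    """Raised with the full list of config violations."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid run configuration:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


@dataclass
class RunConfig:
    """Validated run configuration."""

    stages: tuple
    seed: int
    out_dir: Path
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    module: int | None = None
    base_dir: Path = Path(".")

    def input_path(self, key: str):
        value = self.inputs.get(key)
        if value is None:
            return None
        if isinstance(value, dict):
            return {k: self._resolve(v) for k, v in value.items()}
        return self._resolve(value)

    def _resolve(self, p):
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p


def _check_paths(inputs: dict, base: Path, problems: list) -> None:
    for key, value in inputs.items():
        paths = value.values() if isinstance(value, dict) else [value]
        for p in paths:
            full = Path(p) if Path(p).is_absolute() else base / p
            if not full.exists():
                problems.append(f"inputs.{key}: path does not exist: {p}")


def validate_config(path: str | os.PathLike) -> RunConfig:
    """Load and validate a YAML run config, reporting every violation."""
    path = Path(path)
    problems: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError([f"config file not found: {path}"])
    except yaml.YAMLError as exc:
        raise ConfigError([f"not valid YAML: {exc}"])
    if raw is None:
        raise ConfigError(["config file is empty"])
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    unknown = set(raw) - _KNOWN_TOP
    for key in sorted(unknown):
        problems.append(f"unknown top-level key {key!r}")

    module = raw.get("module")
    stages = raw.get("stages")
    if module is None and stages is None:
        problems.append("one of 'module' (1-6) or 'stages' is required")
    if module is not None and stages is not None:
        problems.append("'module' and 'stages' are mutually exclusive")
    if module is not None:
        if module not in PRESETS:
            problems.append(f"module must be one of {sorted(PRESETS)}, got {module!r}")
        else:
            stages = PRESETS[module]
    if stages is not None and module is None:
        bad = [s for s in stages if s not in STAGES]
        for s in bad:
            problems.append(f"unknown stage {s!r} (known: {', '.join(STAGES)})")
        stages = tuple(s for s in STAGES if s in set(stages))

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")
        seed = 0
    out_dir = raw.get("out_dir")
    if not out_dir:
        problems.append("out_dir is required")
        out_dir = "out"

    inputs = raw.get("inputs") or {}
    if not isinstance(inputs, dict):
        problems.append("inputs must be a mapping")
        inputs = {}
    for key in sorted(set(inputs) - _KNOWN_INPUTS):
        problems.append(f"unknown input key {key!r}")
    params = raw.get("params") or {}
    if not isinstance(params, dict):
        problems.append("params must be a mapping")
        params = {}
    for key in sorted(set(params) - _KNOWN_PARAMS):
        problems.append(f"unknown parameter {key!r}")

    base = path.parent
    if stages:
        required: set = set()
        for stage in stages:
            required |= set(_STAGE_INPUTS.get(stage, ()))
        if module in _PRESET_EXTRA_INPUTS:
            required |= set(_PRESET_EXTRA_INPUTS[module])
        if module is None and "da" in stages and "profile" not in stages:
            required |= {"layers", "annotations"}
        for key in sorted(required):
            if key not in inputs:
                problems.append(
                    f"stage requirements: input {key!r} is required for stages {list(stages)}"
                )
        _check_paths(inputs, base, problems)

    if "da" in (stages or ()) or "pathway" in (stages or ()):
        if "phenotype" not in params:
            problems.append("params.phenotype is required for da/pathway stages")
    if "pathway" in (stages or ()) and "groups" in params:
        groups = params["groups"]
        if not (isinstance(groups, (list, tuple)) and len(groups) == 2):
            problems.append("params.groups must be a 2-item list [groupA, groupB]")
    if "top_n" in params and (not isinstance(params["top_n"], int) or params["top_n"] < 1):
        problems.append("params.top_n must be a positive integer")

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        stages=tuple(stages),
        seed=seed,
        out_dir=Path(out_dir) if Path(out_dir).is_absolute() else base / out_dir,
        inputs=inputs,
        params=params,
        module=module,
        base_dir=base,
    )
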