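"""Pipeline configuration: a small, strictly validated YAML schema.

Unknown keys, duplicated keys, out-of-range values and missing input files
are all rejected before any computation starts, with every problem listed in
one error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(
            f"  - {p}" for p in problems))


class _DuplicateKeyLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicated mapping keys, reporting both lines."""


def _construct_mapping(loader, node, deep=False):
    seen: dict = {}
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            first = seen[key].start_mark.line + 1
            second = key_node.start_mark.line + 1
            raise yaml.YAMLError(
                f"duplicated key {key!r} (lines {first} and {second})")
        seen[key] = key_node
    return yaml.SafeLoader.construct_mapping(loader, node, deep=deep)


_DuplicateKeyLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping)


@dataclass
class PipelineConfig:
    """Typed, defaulted pipeline parameters."""

    out_dir: str = "lipscout_out"
    # input paths (None -> stage runs on synthetic data / is skipped)
    fasta: str | None = None
    darts_counts: str | None = None
    lane_profile: str | None = None
    areas: str | None = None
    annotations: str | None = None
    active_sites: str | None = None
    # digestion / modification
    enzyme: str = "trypsin"
    max_missed: int = 2
    carbamidomethyl: bool = True
    # planner
    transitions_per_precursor: int = 3
    min_peptide_length: int = 7
    max_peptide_length: int = 25
    min_precursor_mz: float = 300.0
    max_precursor_mz: float = 1250.0
    precursor_charge: int = 2
    # statistics
    concentrations: list[float] = field(default_factory=lambda: [1.0, 10.0])
    alpha: float = 0.05
    band_increase_threshold: float = 0.20
    # simulation
    seed: int = 42

    _PATH_FIELDS = ("fasta", "darts_counts", "lane_profile", "areas",
                    "annotations", "active_sites")

    def validate(self) -> list[str]:
        problems = []
        if not 0 < self.alpha < 1:
            problems.append(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.transitions_per_precursor < 1:
            problems.append("transitions_per_precursor must be >= 1")
        if self.max_missed < 0:
            problems.append("max_missed must be >= 0")
        if self.enzyme not in ("trypsin", "trypsin/lysc"):
            problems.append(f"unknown enzyme {self.enzyme!r}")
        if not self.concentrations:
            problems.append("concentrations must be non-empty")
        if self.band_increase_threshold < 0:
            problems.append("band_increase_threshold must be >= 0")
        if self.min_peptide_length < 2:
            problems.append("min_peptide_length must be >= 2")
        if self.precursor_charge < 1:
            problems.append("precursor_charge must be >= 1")
        for name in self._PATH_FIELDS:
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                problems.append(f"{name}: file not found: {value}")
        return problems


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config file into a :class:`PipelineConfig`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        with open(path) as handle:
            raw = yaml.load(handle, Loader=_DuplicateKeyLoader)
    except yaml.YAMLError as exc:
        raise ConfigError([str(exc)]) from None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a key-value mapping"])
    known = {f.name for f in fields(PipelineConfig) if not f.name.startswith("_")}
    problems = [f"unknown key {k!r}" for k in raw if k not in known]
    if problems:
        raise ConfigError(problems)
    cfg = PipelineConfig(**raw)
    problems = cfg.validate()
    if problems:
        raise ConfigError(problems)
    return cfg
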