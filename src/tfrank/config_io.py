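"""Helpers turning a generated scenario into a runnable pipeline config."""

from __future__ import annotations

from pathlib import Path

import yaml

from .simulate import Scenario

__all__ = ["write_scenario_config", "scenario_config_dict"]


def scenario_config_dict(scenario: Scenario, **parameter_overrides) -> dict:
    """Pipeline configuration (relative paths) for a generated scenario."""
    root = scenario.root
    peaks: dict[str, dict[str, list[str]]] = {}
    for (group, assay), path in scenario.peak_beds.items():
        peaks.setdefault(group, {})[assay] = [str(path.relative_to(root))]
    cfg = {
        "genome": str(scenario.genome_fasta.relative_to(root)),
        "annotation": str(scenario.annotation.relative_to(root)),
        "motifs": str(scenario.motifs.relative_to(root)),
        "counts": str(scenario.counts.relative_to(root)),
        "sample_groups": dict(scenario.sample_groups),
        "peaks": peaks,
        "condition_pairs": [list(scenario.config.groups)],
    }
    if parameter_overrides:
        cfg["parameters"] = dict(parameter_overrides)
    return cfg


def write_scenario_config(scenario: Scenario, **parameter_overrides) -> Path:
    cfg = scenario_config_dict(scenario, **parameter_overrides)
    path = scenario.root / "config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
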