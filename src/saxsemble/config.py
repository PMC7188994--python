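"""Run configuration: declarative YAML in, validated dataclass out.

Defaults encode the analysis settings used throughout the package:
clustering cutoff 1.5 Å, 20,000 Metropolis steps, usable q range
0.01–0.2 Å⁻¹, ENM mode rank 7 at a 12 Å cutoff.  ``validate_config``
returns the full list of violations rather than stopping at the first.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "validate_config"]


@dataclass
class RunConfig:
    # input paths; all optional — absent inputs switch to the synthetic demo
    structure_path: str | None = None
    ensemble_path: str | None = None
    experiment_path: str | None = None

    # selectors for the active-site observables
    catalytic_residue: int | None = None
    catalytic_chain: str | None = None
    substrate_resname: str = "SUB"
    cofactor_resname: str | None = None

    # analysis settings (printed defaults of the study design)
    cluster_cutoff: float = 1.5
    q_min: float = 0.01
    q_max: float = 0.20
    q_points: int = 100
    mc_steps: int = 20000
    seed: int = 1
    proposal_scale: float = 0.05
    enm_cutoff: float = 12.0
    mode_rank: int = 7
    representation: str = "residue-bead"

    # synthetic-demo settings
    demo_n_frames: int = 600
    demo_populations: tuple[float, ...] = (0.08, 0.75, 0.17)
    demo_jitter_sigma: float = 0.1
    demo_noise_fraction: float = 0.01

    # stage toggles and output
    stages: tuple[str, ...] = (
        "distances", "cluster", "profile", "simulate", "fit", "modes"
    )
    output_dir: str = "saxsemble_out"


_KNOWN_STAGES = {"distances", "align", "cluster", "profile", "simulate",
                 "fit", "modes"}


def validate_config(config: RunConfig) -> tuple[RunConfig, list[str]]:
    """Check all constraints; returns (config, list of violation messages)."""
    errors: list[str] = []
    for name in ("structure_path", "ensemble_path", "experiment_path"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            errors.append(f"{name}: path {value!r} does not exist")
    if config.cluster_cutoff <= 0:
        errors.append("cluster_cutoff: must be positive")
    if not 0 < config.q_min < config.q_max:
        errors.append("q_min/q_max: need 0 < q_min < q_max")
    if config.q_points < 2:
        errors.append("q_points: need at least 2")
    if config.mc_steps < 1:
        errors.append("mc_steps: must be at least 1")
    if config.enm_cutoff <= 0:
        errors.append("enm_cutoff: must be positive")
    if config.mode_rank < 1:
        errors.append("mode_rank: must be at least 1")
    if config.demo_n_frames < 1:
        errors.append("demo_n_frames: must be at least 1")
    pops = config.demo_populations
    if any(p < 0 for p in pops) or abs(sum(pops) - 1.0) > 1e-9:
        errors.append("demo_populations: must be nonnegative and sum to 1")
    if config.representation not in ("residue-bead", "all-atom-constant-f"):
        errors.append(f"representation: unknown {config.representation!r}")
    unknown = set(config.stages) - _KNOWN_STAGES
    if unknown:
        errors.append(f"stages: unknown stage(s) {sorted(unknown)}")
    return config, errors


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file (empty/absent file → all defaults)."""
    data: dict = {}
    if path is not None:
        try:
            raw = Path(path).read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {path} must be a mapping")
        data = loaded
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid_names = {f.name for f in fields(RunConfig)}
    unknown = set(data) - valid_names
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    if "demo_populations" in data:
        data["demo_populations"] = tuple(data["demo_populations"])
    config = RunConfig(**data)
    config, errors = validate_config(config)
    if errors:
        raise ConfigError("; ".join(errors))
    return config
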