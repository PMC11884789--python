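"""Run configuration: YAML loading, validation and defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .simulate import SimConfig


@dataclass
class RunConfig:
    """All tunables of one end-to-end run.

    Caller parameters (window/step/q/min_support) and annotation windows
    default to the values used throughout the package: 200/100 bp windows,
    q <= 0.001, support >= 3 of 4 replicates, promoter -2500/+500 and
    downstream -500/+2500 around TSS/TTS, +-1 kb TF-peak proximity margin.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    q_threshold: float = 0.001
    min_support: int = 3
    window_size: int = 200
    step: int = 100
    min_score: int = 20
    promoter_upstream: int = 2500
    promoter_downstream: int = 500
    downstream_upstream: int = 500
    downstream_downstream: int = 2500
    proximity_margin: int = 1000
    flank: int = 5000
    profile_bins: int = 100
    pca_bin: int = 500
    seed: int = 0

    def validate(self) -> list[str]:
        errors = []
        if not (0 < self.q_threshold <= 1):
            errors.append(f"q_threshold must be in (0, 1], got {self.q_threshold}")
        if self.min_support < 1:
            errors.append("min_support must be >= 1")
        if self.window_size <= 0 or self.step <= 0:
            errors.append("window_size and step must be positive")
        if self.flank <= 0 or (2 * self.flank) % self.profile_bins != 0:
            errors.append("2 * flank must be a positive multiple of profile_bins")
        if self.pca_bin < 1:
            errors.append("pca_bin must be >= 1")
        try:
            self.sim.validate()
        except ValueError as exc:
            errors.append(str(exc))
        return errors

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(path: str) -> RunConfig:
    """Load a YAML config, inject defaults, and range-check every field.

    Raises ValueError listing every problem found (aggregated, one per line).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {})
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    errors = [f"unknown config key {k!r}" for k in sorted(unknown)]
    for k in unknown:
        raw.pop(k)
    unknown_sim = set(sim_raw) - set(SimConfig.__dataclass_fields__)
    errors += [f"unknown sim key {k!r}" for k in sorted(unknown_sim)]
    for k in unknown_sim:
        sim_raw.pop(k)
    cfg = RunConfig(sim=SimConfig(**sim_raw), **raw)
    if "seed" in sim_raw and "seed" not in raw:
        cfg.seed = cfg.sim.seed
    cfg.sim.seed = cfg.seed if "seed" not in sim_raw else cfg.sim.seed
    errors += cfg.validate()
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    return cfg
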