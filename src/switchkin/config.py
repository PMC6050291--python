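"""Configuration objects for the synthetic-data generators.

Both configs are plain dataclasses that validate on construction and
round-trip through flat YAML mappings (`from_yaml` / `to_yaml`), so every
run directory can carry a verbatim echo of the parameters that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: Canonical state order used throughout: [L,L], [H,L], [L,H], [H,H],
#: with per-state emission means given as (cro, ci) molecules/frame.
STATE_NAMES = ("[L,L]", "[H,L]", "[L,H]", "[H,H]")

DEFAULT_EMISSION_MEANS = ((0.0, 0.0), (5.2, 0.0), (0.0, 4.7), (4.5, 4.7))
DEFAULT_DWELL_MEANS = (7.0, 36.0, 127.0, 47.0)
DEFAULT_STATIONARY_TARGETS = (
    391 / 8338,
    1733 / 8338,
    3145 / 8338,
    3069 / 8338,
)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the lineage/trace generator.

    ``emission_means`` are per-state ``(lambda_cro, lambda_ci)`` pairs in
    molecules/frame; ``dwell_means`` are per-state mean dwell times in
    minutes; ``stationary_targets`` (optional) are the per-state fractions
    of frames the calibrated chain should occupy at stationarity.
    """

    frame_interval: float = 5.0
    n_lineages: int = 94
    trace_length: int = 69
    cell_cycle_mean: float = 71.0
    cell_cycle_sd: float = 22.0
    emission_means: tuple = DEFAULT_EMISSION_MEANS
    dwell_means: tuple = DEFAULT_DWELL_MEANS
    stationary_targets: tuple | None = DEFAULT_STATIONARY_TARGETS
    maturation_mean: float = 0.0
    detection_efficiency: float = 1.0
    emission_family: str = "poisson"
    nb_dispersion: float = 10.0
    rng_seed: int = 0

    def __post_init__(self):
        self.emission_means = tuple(
            (float(a), float(b)) for a, b in self.emission_means
        )
        self.dwell_means = tuple(float(d) for d in self.dwell_means)
        if self.stationary_targets is not None:
            self.stationary_targets = tuple(
                float(p) for p in self.stationary_targets
            )
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.emission_means)

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")
        if self.n_lineages < 0:
            raise ConfigError("n_lineages must be >= 0")
        if self.trace_length < 1:
            raise ConfigError("trace_length must be >= 1")
        if self.cell_cycle_mean <= 0:
            raise ConfigError("cell_cycle_mean must be > 0")
        if self.cell_cycle_sd < 0:
            raise ConfigError("cell_cycle_sd must be >= 0")
        means = np.asarray(self.emission_means, dtype=float)
        if means.ndim != 2 or means.shape[1] != 2:
            raise ConfigError("emission_means must be (lambda_cro, lambda_ci) pairs")
        if np.any(means < 0):
            raise ConfigError("emission means must be >= 0")
        dwell = np.asarray(self.dwell_means, dtype=float)
        if dwell.shape[0] != means.shape[0]:
            raise ConfigError("dwell_means length must match emission_means")
        if np.any(dwell < self.frame_interval):
            raise ConfigError("dwell means must be >= frame_interval")
        if self.stationary_targets is not None:
            pi = np.asarray(self.stationary_targets, dtype=float)
            if pi.shape[0] != means.shape[0]:
                raise ConfigError("stationary_targets length must match states")
            if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
                raise ConfigError("stationary_targets must be >= 0 and sum to 1")
        if not (0.0 < self.detection_efficiency <= 1.0):
            raise ConfigError("detection_efficiency must be in (0, 1]")
        if self.maturation_mean < 0:
            raise ConfigError("maturation_mean must be >= 0")
        if self.emission_family not in ("poisson", "negative_binomial"):
            raise ConfigError("emission_family must be 'poisson' or 'negative_binomial'")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["emission_means"] = [list(p) for p in self.emission_means]
        d["dwell_means"] = list(self.dwell_means)
        if self.stationary_targets is not None:
            d["stationary_targets"] = list(self.stationary_targets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


@dataclass
class MechanismConfig:
    """Parameters of the mechanistic operator-occupancy simulator.

    Per-operator rates are 3-vectors over (O_R1, O_R2, O_R3). Binding
    propensity for n free repressor molecules is ``rate * n * (n - 1) / 2``
    (dimer-like association), which keeps a small repressor leak from
    silencing the opposing promoter. ``adiabaticity_scale`` multiplies all
    binding AND unbinding rates, changing the operator timescale without
    moving its equilibrium. Defaults are illustrative, not fitted.
    """

    ci_on: tuple = (0.049, 0.0, 0.0)
    ci_off: tuple = (1.0, 1.0, 1.0)
    cro_on: tuple = (0.0, 0.0, 0.049)
    cro_off: tuple = (1.0, 1.0, 1.0)
    k_pr: float = 12.0
    k_prm: float = 12.0
    mrna_lifetime: float = 1.5
    burst_size: float = 0.25
    protein_lifetime: float = 25.0
    adiabaticity_scale: float = 1.0
    init_ci: int = 40
    init_cro: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        self.ci_on = tuple(float(x) for x in self.ci_on)
        self.ci_off = tuple(float(x) for x in self.ci_off)
        self.cro_on = tuple(float(x) for x in self.cro_on)
        self.cro_off = tuple(float(x) for x in self.cro_off)
        self.validate()

    def validate(self) -> None:
        for name in ("ci_on", "ci_off", "cro_on", "cro_off"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ConfigError(f"{name} must have one rate per operator (3)")
            if np.any(v < 0):
                raise ConfigError(f"{name} rates must be >= 0")
        for name in ("k_pr", "k_prm", "burst_size", "adiabaticity_scale"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.mrna_lifetime <= 0:
            raise ConfigError("mrna_lifetime must be > 0")
        if self.protein_lifetime <= 0:
            raise ConfigError("protein_lifetime must be > 0")
        if self.init_ci < 0 or self.init_cro < 0:
            raise ConfigError("initial protein counts must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("ci_on", "ci_off", "cro_on", "cro_off"):
            d[name] = list(getattr(self, name))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MechanismConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MechanismConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
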