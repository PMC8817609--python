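"""Run configuration: defaults, TOML loading, and lossless round-tripping.

Precedence everywhere in the CLI is flags > config file > defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, replace

from .errors import InvalidParameterError


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a pipeline run, grouped by owning module."""

    # solver
    step_mm: float = 0.5
    k_expansion: float = 1.0
    measurement_offset_mm: float = 30.0
    # boundary conditions
    flow_coefficient: float = 3.41
    flow_exponent: float = 0.75
    murray_exponent: float = 3.0
    hyperemic_factor: float = 3.0
    blood_density: float = 1056.0
    blood_viscosity: float = 0.0035
    # cutoffs
    index_cutoff: float = 0.89
    ifr_cutoff: float = 0.89
    ffr_cutoff: float = 0.80
    # cohort
    n_vessels: int = 36
    sigma_ifr: float = 0.02
    sigma_ffr: float = 0.03
    # run control
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        positive = ["step_mm", "k_expansion", "measurement_offset_mm",
                    "flow_coefficient", "murray_exponent", "blood_density",
                    "blood_viscosity"]
        bad = [k for k in positive if getattr(self, k) <= 0]
        if self.hyperemic_factor < 1:
            bad.append("hyperemic_factor")
        for k in ("index_cutoff", "ifr_cutoff", "ffr_cutoff"):
            if not 0 < getattr(self, k) < 1:
                bad.append(k)
        if self.n_vessels < 1:
            bad.append("n_vessels")
        if self.sigma_ifr < 0 or self.sigma_ffr < 0:
            bad.append("sigma_ifr/sigma_ffr")
        if bad:
            raise InvalidParameterError(f"config fields out of range: {bad}")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_toml(self) -> str:
        lines = []
        for k, v in self.to_dict().items():
            if isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{k} = {str(v).lower()}")
            elif isinstance(v, int):
                lines.append(f"{k} = {v}")
            else:
                lines.append(f"{k} = {v!r}")
        return "\n".join(lines) + "\n"


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def with_overrides(cfg: RunConfig, **overrides) -> RunConfig:
    """Apply non-None overrides (CLI flags) on top of a config."""
    clean = {k: v for k, v in overrides.items() if v is not None}
    return replace(cfg, **clean) if clean else cfg
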