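"""Experiment configuration: schema, validation and file loading."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .templates import COPOLYMER_SPECIES, endcaps_per_chain

TRIGGER_MODES = ("stoichiometric", "constant", "none")


@dataclass
class ExperimentSpec:
    """One cell of the scenario matrix: architecture x cargo x trigger dose.

    ``trigger_mode='stoichiometric'`` doses one trigger per end-cap
    (chains x end-caps per chain); ``'constant'`` uses ``trigger_count``
    directly, matching the reference dose of four triggers per chain when
    left unset.  Protocol stage lengths are the full-scale counts; the
    desk ``scale_factor`` divides them.
    """

    architecture: str = "A30B30"
    n_chains: int = 1000
    cargo_count: int = 2000
    phi: float = 0.12
    tstar_map: dict = field(default_factory=dict)
    trigger_mode: str = "stoichiometric"
    trigger_count: int | None = None
    rp_t: float = 1e-4
    rp_b: float = 1e-3
    attempt_every: int = 100
    consume_trigger: bool = True
    detached_bead_fate: str = "keep_type"
    dt: float = 0.006
    tstar: float = 1.8
    gamma: float = 1.0
    n_pushoff: int = 2_000_000
    n_equil: int = 30_000_000
    n_prod: int = 300_000_000
    n_reaction_steps: int = 300_000_000
    snapshot_every: int = 100_000
    scale_factor: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.architecture not in COPOLYMER_SPECIES:
            raise ValueError(f"architecture must be one of {COPOLYMER_SPECIES}, "
                             f"got {self.architecture!r}")
        if self.trigger_mode not in TRIGGER_MODES:
            raise ValueError(f"trigger_mode must be one of {TRIGGER_MODES}")
        for name in ("rp_t", "rp_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} is not a probability")
        if not 0.0 < self.phi < 0.5:
            raise ValueError("phi must lie in (0, 0.5)")
        if self.n_chains < 1 or self.cargo_count < 0:
            raise ValueError("need at least one chain and a non-negative cargo count")
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory (reproducibility contract)")
        if self.trigger_mode == "constant" and self.trigger_count is None:
            self.trigger_count = 4 * self.n_chains
        if self.trigger_mode == "stoichiometric":
            stoich = self.n_chains * endcaps_per_chain(self.architecture)
            if self.trigger_count is None:
                self.trigger_count = stoich
            elif self.trigger_count != stoich:
                raise ValueError(
                    f"stoichiometric mode requires trigger_count = chains x "
                    f"end-caps = {stoich}, got {self.trigger_count}")
        if self.trigger_mode == "none":
            self.trigger_count = 0

    @property
    def endcaps_per_chain(self) -> int:
        return endcaps_per_chain(self.architecture)

    def resolved(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> ExperimentSpec:
    """Load a TOML or YAML experiment file into a validated spec.

    Unknown keys are rejected with a field-level message; defaults are
    filled and the fully resolved spec is what downstream stages see.
    """
    path = Path(path)
    if path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    elif path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
    else:
        raise ValueError(f"unsupported config format {path.suffix!r} (use TOML or YAML)")
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = set(ExperimentSpec.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentSpec(**raw)


def save_resolved_config(spec: ExperimentSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.resolved(), sort_keys=True))
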