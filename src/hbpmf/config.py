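"""Run configuration: protocol, potentials, screening thresholds, seeds.

Defaults mirror the measurement conditions the analysis assumes: 25 pulling
replicates per interaction, a 500 kcal/mol/Å² spring moving at 0.5 Å/ns from
2.5 to 5.0 Å at 298 K, 50 bootstrap resamples, α = 0.05 significance and a
0.5 Pearson threshold for the rupture-correlation screen.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .synthetic_smd import ToyHBondPotential
from .work_model import PullingProtocol, ValidationError

__all__ = ["InteractionSpec", "RunConfig"]


@dataclass(frozen=True)
class InteractionSpec:
    """One measured interaction: an id plus optional potential overrides.

    Overrides apply on top of the per-condition potential (e.g. a deeper
    well for a buried bond); ``correlated_with`` optionally names another
    interaction and a target rupture-distance correlation, letting a config
    express the correlated-contact geometry the screen must catch.
    """

    id: str
    potential_overrides: dict = field(default_factory=dict)
    correlated_with: str | None = None
    rho: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a simulate→estimate→screen→aggregate run."""

    system: str = "demo"
    interactions: tuple = (InteractionSpec("bond_1"), InteractionSpec("bond_2"))
    protocol: PullingProtocol = field(default_factory=PullingProtocol)
    potentials: dict = field(default_factory=lambda: {
        "binary": ToyHBondPotential(),
        "ternary": ToyHBondPotential(shielding=0.6),
    })
    n_replicates: int = 25
    n_bootstrap: int = 50
    alpha: float = 0.05
    correlation_threshold: float = 0.5
    base_seed: int = 20260101

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be ≥ 1")
        if self.n_bootstrap < 2:
            raise ValidationError("n_bootstrap must be ≥ 2")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 < self.correlation_threshold <= 1:
            raise ValidationError("correlation_threshold must lie in (0, 1]")
        if set(self.potentials) != {"binary", "ternary"}:
            raise ValidationError("potentials must define 'binary' and 'ternary'")
        object.__setattr__(self, "interactions", tuple(
            i if isinstance(i, InteractionSpec) else InteractionSpec(**i)
            for i in self.interactions))

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "system": self.system,
            "interactions": [asdict(i) for i in self.interactions],
            "protocol": asdict(self.protocol),
            "potentials": {k: asdict(v) for k, v in self.potentials.items()},
            "n_replicates": self.n_replicates,
            "n_bootstrap": self.n_bootstrap,
            "alpha": self.alpha,
            "correlation_threshold": self.correlation_threshold,
            "base_seed": self.base_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "protocol" in d:
            d["protocol"] = PullingProtocol(**d["protocol"])
        if "potentials" in d:
            d["potentials"] = {k: ToyHBondPotential(**v)
                               for k, v in d["potentials"].items()}
        if "interactions" in d:
            d["interactions"] = tuple(
                InteractionSpec(**i) if isinstance(i, dict) else i
                for i in d["interactions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True),
                        encoding="utf-8")
        return path

    def config_hash(self) -> str:
        """Stable short hash of the canonical config serialisation."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, base_seed=int(seed))
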