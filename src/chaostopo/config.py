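"""Run configuration: one serializable object describing a whole run.

A RunConfig pins every tunable of the pipeline — kernel, filtration,
oscillator, integration, feature and learning settings plus the global
seed — and hashes canonically, so any two runs with equal configs (and
equal inputs) are bitwise reproducible and artifacts can be audited by
their config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # connectivity kernel
    kernel: str = "exponential"
    sigma: float = 3.0
    kappa: int = 1
    nu: float = 2.0
    cutoff: float | None = None
    absolute_pcc: bool = True
    # filtration
    p: int = 10
    weighted: bool = False
    attractive: bool = True
    alpha_grid: list[float] = field(default_factory=list)
    # oscillator + coupling
    model: str = "lorenz"
    epsilon: float = 13.6
    lorenz_alpha: float = 10.0
    lorenz_gamma: float = 60.0
    lorenz_beta: float = 8.0 / 3.0
    rossler_a: float = 0.1
    rossler_b: float = 0.1
    rossler_c: float = 4.0
    # integration
    scheme: str = "rk4"
    h: float = 1e-3
    n_steps: int = 20_000
    transient: int | None = None
    # features
    stats: list[str] = field(
        default_factory=lambda: [
            "mean", "std", "min", "max", "median", "skewness", "kurtosis",
        ]
    )
    mode: str = "perturbative"
    # learning
    ml_model: str = "knn"
    folds: int = 10
    seeds: list[int] = field(default_factory=lambda: list(range(10)))
    # global
    seed: int = 0

    def oscillator_spec(self):
        from .dynamics import OscillatorSpec

        return OscillatorSpec(
            model=self.model,
            alpha=self.lorenz_alpha,
            gamma=self.lorenz_gamma,
            beta=self.lorenz_beta,
            a=self.rossler_a,
            b=self.rossler_b,
            c=self.rossler_c,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
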