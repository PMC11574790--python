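"""Demographic and game parameters for the territory-competition model.

The model tracks a single-sex population of territorial birds in which
reproduction requires holding a breeding territory.  Four parameters govern
the dynamics:

``b``
    chick survival, i.e. the probability that the single chick produced by a
    territory holder matures and survives to the next year (per year,
    dimensionless).  With an equal sex ratio this corresponds to a chick
    survival of ``2b`` in the full two-sex population.
``mu``
    per-capita mortality rate (per year); ``1/mu`` is the mean lifespan.
``c``
    injury-risk scalar: the expected fraction of hawk-hawk encounters that
    leave an aggressive individual too wounded to breed this year.
``territory_km2``
    mean breeding-territory area in km²; it converts island area into the
    number of available territories.

Defaults are tailored to large flightless island pigeons (dodo/solitaire
scale): 30-year lifespan, one egg per year with 0.15 effective chick
survival, 0.104 km² territories, and an injury scalar of 2.5e-4.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelParams", "PAYOFF_MATRIX"]

#: Hawk-Dove win-probability matrix, rows/cols ordered (aggressive, non-aggressive).
#: Entry [i, j] is the probability that a strategy-i bird wins a territory
#: contest against a strategy-j bird.  Costs of fighting are *not* folded into
#: the payoffs; injuries are charged separately through ``c``.
PAYOFF_MATRIX = np.array([[0.5, 1.0], [0.0, 0.5]])


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Parameter set for the population model.

    Raises ``ValueError`` for non-viable or non-physical combinations
    (requires ``0 < mu < b <= 1``, ``c >= 0``, ``territory_km2 > 0``).
    """

    b: float = 0.15
    mu: float = 1.0 / 30.0
    c: float = 0.00025
    territory_km2: float = 0.104

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < self.b <= 1.0):
            raise ValueError(
                f"need 0 < mu < b <= 1 for a viable population, got "
                f"mu={self.mu}, b={self.b}"
            )
        if self.c < 0.0:
            raise ValueError(f"injury scalar c must be >= 0, got {self.c}")
        if self.territory_km2 <= 0.0:
            raise ValueError(
                f"territory area must be positive, got {self.territory_km2}"
            )

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        """Load parameters from a YAML config with a ``model:`` block.

        Expected layout::

            model:
              b: 0.15
              mu: 0.0333333
              c: 0.00025
              territory_km2: 0.104

        Missing keys fall back to the defaults.
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        block = cfg.get("model", cfg)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**block)
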