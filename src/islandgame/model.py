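"""Discrete-time population dynamics with Hawk-Dove territory competition.

Two deterministic annual maps are provided:

* a single-strategy model of a non-aggressive population whose reproduction
  is limited by the smaller of the population size and the number of
  breeding territories, and
* a two-strategy extension tracking aggressive ("hawk", escalates contests,
  risks injury) and non-aggressive ("dove", yields contests) individuals,
  where the classic Hawk-Dove win probabilities set how the territories are
  divided and injuries among hawks are charged as a separate demographic
  cost (wounded hawks skip breeding for one year).

Populations and territory counts are real-valued: the model is a
deterministic mean-field map with no demographic stochasticity, and the
territory count ``K`` derived from island area is deliberately not rounded.
Territories are redistributed every year; floaters (birds without a
territory) and healed wounded compete again the following year.

Time is measured in years before present (BP), decreasing toward 0.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "PopulationState",
    "TerritorySeries",
    "Trajectory",
    "territories_from_area",
    "payoff_shares",
    "wounded_count",
    "birth_terms",
    "step_single_strategy",
    "step_two_strategy",
    "simulate",
]


@dataclasses.dataclass(frozen=True)
class PopulationState:
    """Counts of aggressive (``NA``) and non-aggressive (``NF``) birds at ``t`` (years BP)."""

    NA: float
    NF: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.NA < 0 or self.NF < 0:
            raise ValueError(f"population counts must be >= 0, got NA={self.NA}, NF={self.NF}")
        if self.t < 0:
            raise ValueError(f"time must be >= 0 years BP, got {self.t}")

    @property
    def n(self) -> float:
        """Total population size."""
        return self.NA + self.NF

    @property
    def f_aggressive(self) -> float:
        """Aggressive fraction fA = NA / (NA + NF); undefined (NaN) for an empty population."""
        n = self.n
        return self.NA / n if n > 0 else float("nan")


@dataclasses.dataclass(frozen=True)
class TerritorySeries:
    """Annual territory counts K(t) on a strictly decreasing years-BP axis."""

    times_ybp: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ybp, dtype=float)
        k = np.asarray(self.K, dtype=float)
        if t.shape != k.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times_ybp and K must be equal-length 1-D arrays")
        if not np.all(np.diff(t) < 0):
            raise ValueError("times must be strictly decreasing (years BP toward present)")
        if np.any(k < 0) or not np.all(np.isfinite(k)):
            raise ValueError("territory counts must be finite and >= 0")
        object.__setattr__(self, "times_ybp", t)
        object.__setattr__(self, "K", k)

    def __len__(self) -> int:
        return self.times_ybp.size


@dataclasses.dataclass
class Trajectory:
    """Simulation output: annual records of state and diagnostics.

    ``floaters`` is the excess of birds over territories, max(0, N - K);
    ``wounded`` is the number of hawks injured out of breeding that year.
    """

    t_ybp: np.ndarray
    NA: np.ndarray
    NF: np.ndarray
    K: np.ndarray
    floaters: np.ndarray
    wounded: np.ndarray

    @property
    def N(self) -> np.ndarray:
        return self.NA + self.NF

    @property
    def f_aggressive(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.N > 0, self.NA / self.N, np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ybp": self.t_ybp,
                "NA": self.NA,
                "NF": self.NF,
                "K": self.K,
                "floaters": self.floaters,
                "wounded": self.wounded,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def territories_from_area(area_km2, params: ModelParams):
    """Number of breeding territories supported by an island of the given area.

    K = area / territory_km2, left continuous (not floored): the analytic
    equilibria of the model presuppose a real-valued K.  Accepts scalars or
    arrays; negative areas raise.
    """
    area = np.asarray(area_km2, dtype=float)
    if np.any(area < 0):
        raise ValueError("island area must be >= 0")
    k = area / params.territory_km2
    return float(k) if np.isscalar(area_km2) else k


def payoff_shares(NA: float, NF: float) -> tuple[float, float]:
    """Fractions (pA, pF) of territories won by hawks and doves.

    Derived from the Hawk-Dove win probabilities: hawks beat doves outright,
    like strategies split 50/50, and a bird does not compete with itself
    (hence the ``N - 1`` self-exclusion terms, clamped at 0 for fractional
    counts below one individual).  The two shares sum to exactly 1 whenever
    any contest happens; an empty population returns (0, 0) with a warning.
    """
    if NA < 0 or NF < 0:
        raise ValueError("counts must be >= 0")
    n = NA + NF
    if n == 0:
        warnings.warn("payoff_shares called with an empty population; no territories contested")
        return (0.0, 0.0)
    num_a = (0.5 * max(NA - 1.0, 0.0) + NF) * NA
    num_f = 0.5 * max(NF - 1.0, 0.0) * NF
    den = num_a + num_f
    if den == 0.0:
        # fewer than ~one bird per strategy: no pairwise contests, split by headcount
        return (NA / n, NF / n)
    return (num_a / den, num_f / den)


def wounded_count(NA: float, params: ModelParams) -> float:
    """Expected number of hawks wounded out of breeding this year.

    The expected casualty count c*(NA-1)*NA is a linear-in-encounters
    approximation and would exceed the population for NA > ~1/c, so it is
    clamped to [0, NA].  Wounded birds survive, skip breeding once, and
    compete again next year.
    """
    if NA < 0:
        raise ValueError("NA must be >= 0")
    return min(NA, max(0.0, params.c * (NA - 1.0) * NA))


def birth_terms(state: PopulationState, K: float, params: ModelParams) -> tuple[float, float]:
    """Recruits (BA, BF) produced by each strategy this year.

    Each strategy's breeding pool is the smaller of its share of territories
    and its available (unwounded) individuals; recruits are the pool times
    chick survival ``b``.  The min() form coincides with the piecewise
    territory-/individual-limited cases, including at the tie.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if state.n == 0:
        return (0.0, 0.0)
    pA, pF = payoff_shares(state.NA, state.NF)
    W = wounded_count(state.NA, params)
    BA = params.b * max(0.0, min(pA * K, state.NA - W))
    BF = params.b * max(0.0, min(pF * K, state.NF))
    return (BA, BF)


def step_single_strategy(N: float, K: float, params: ModelParams) -> float:
    """One annual step of the non-aggressive (dove-only) model.

    N' = b*min(N, K) + (1 - mu)*N.  For constant K the map converges to the
    carrying capacity N* = b*K/mu, at which only the fraction mu/b of birds
    holds a territory and breeds.
    """
    if N < 0 or K < 0:
        raise ValueError("N and K must be >= 0")
    return params.b * min(N, K) + (1.0 - params.mu) * N


def step_two_strategy(state: PopulationState, K: float, params: ModelParams) -> PopulationState:
    """One annual step of the hawk/dove model.

    Applies territory division (payoff_shares), injuries (wounded_count) and
    recruitment (birth_terms), then adult survival at rate 1 - mu.  With no
    hawks present this reduces exactly to ``step_single_strategy``.  Offspring
    inherit the parental strategy.
    """
    BA, BF = birth_terms(state, K, params)
    s = 1.0 - params.mu
    t_next = max(state.t - 1.0, 0.0)
    return PopulationState(NA=BA + s * state.NA, NF=BF + s * state.NF, t=t_next)


def _step_raw(NA: float, NF: float, K: float, params: ModelParams) -> tuple[float, float]:
    """Two-strategy step on raw floats (no state object); used by the equilibrium solvers.

    Inputs are clamped at 0 so that root-finders may probe slightly outside
    the admissible region.
    """
    NA = max(NA, 0.0)
    NF = max(NF, 0.0)
    n = NA + NF
    if n == 0.0:
        return (0.0, 0.0)
    num_a = (0.5 * max(NA - 1.0, 0.0) + NF) * NA
    num_f = 0.5 * max(NF - 1.0, 0.0) * NF
    den = num_a + num_f
    if den == 0.0:
        pA, pF = NA / n, NF / n
    else:
        pA, pF = num_a / den, num_f / den
    W = min(NA, max(0.0, params.c * (NA - 1.0) * NA))
    BA = params.b * max(0.0, min(pA * K, NA - W))
    BF = params.b * max(0.0, min(pF * K, NF))
    s = 1.0 - params.mu
    return (BA + s * NA, BF + s * NF)


def simulate(
    initial: PopulationState,
    series: TerritorySeries,
    params: ModelParams,
) -> Trajectory:
    """Run the two-strategy model over an annual territory series.

    The series supplies K(t) at every year of the simulation window (use
    :func:`islandgame.forcing.interpolate_series` to refine coarser forcing).
    The first record of the trajectory is the initial state at the first
    series time; each subsequent record is one annual step later.  Floater
    and wounded diagnostics are recorded per year.
    """
    times = series.times_ybp
    if abs(initial.t - times[0]) > 1e-9:
        raise ValueError(
            f"initial state time {initial.t} does not match series start {times[0]}"
        )
    dt = np.diff(times)
    if not np.allclose(dt, -1.0):
        raise ValueError("territory series must be annual (1-year steps); interpolate first")

    n_steps = len(series)
    NA = np.empty(n_steps)
    NF = np.empty(n_steps)
    wounded = np.empty(n_steps)
    na, nf = float(initial.NA), float(initial.NF)
    b, mu, c = params.b, params.mu, params.c
    s = 1.0 - mu
    Kv = series.K
    for i in range(n_steps):
        NA[i], NF[i] = na, nf
        w = min(na, max(0.0, c * (na - 1.0) * na))
        wounded[i] = w
        if i == n_steps - 1:
            break
        K = Kv[i]
        n = na + nf
        if n == 0.0:
            continue
        num_a = (0.5 * max(na - 1.0, 0.0) + nf) * na
        num_f = 0.5 * max(nf - 1.0, 0.0) * nf
        den = num_a + num_f
        if den == 0.0:
            pA, pF = na / n, nf / n
        else:
            pA, pF = num_a / den, num_f / den
        BA = b * max(0.0, min(pA * K, na - w))
        BF = b * max(0.0, min(pF * K, nf))
        na = BA + s * na
        nf = BF + s * nf
    floaters = np.maximum(0.0, NA + NF - Kv)
    return Trajectory(t_ybp=times.copy(), NA=NA, NF=NF, K=Kv.copy(), floaters=floaters, wounded=wounded)
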