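"""Fixed points, stability, and the tipping point of the hawk/dove map.

For a fixed number of territories ``K`` the annual map has up to four
equilibria for the aggressive fraction fA = NA/(NA+NF):

* fA = 0 — doves only, at the carrying capacity N* = b*K/mu (a repeller:
  hawks always invade, since they win every contest against a dove);
* fA = 1 — hawks only, self-limited by injuries (an attractor);
* two interior (mixed) equilibria, one stable at low fA and one unstable at
  high fA, which exist only above a critical territory count K*.

The two mixed equilibria collide and vanish at a saddle-node (fold)
bifurcation at K*.  Below K* the only attractor is the all-hawk state, so a
shrinking island that crosses K* tips abruptly and irreversibly into
fixation of aggression; because fA = 1 is absorbing under pure-strategy
inheritance, recovery of the island does not restore non-aggressive birds
(hysteresis).

At an interior equilibrium hawks are limited by their own unwounded count,
which pins the hawk population at NA* = 1 + (b - mu)/(b*c) independent of K,
while doves are territory-limited; eliminating the dove birth share yields a
quadratic for NF* whose discriminant

    (b*K/mu - 1)^2 - 4*(b*K/mu)*(1 + (b - mu)/(b*c))

vanishes exactly at the fold.  Writing x = b*K/mu and A = 1 + (b-mu)/(b*c),
the fold is the larger root of x^2 - (2 + 4A)x + 1 = 0, and the tipping
island area is area* = K* * territory_km2.

Numerics: fixed points are found by root-finding on the 2-D map itself (the
closed form above serves only as an independent cross-check in the test
suite); stability comes from the eigenvalues of a finite-difference Jacobian
of the map.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import optimize

from .model import _step_raw
from .params import ModelParams

__all__ = [
    "FixedPoint",
    "BifurcationResult",
    "equilibrium_population",
    "breeding_fraction",
    "boundary_equilibria",
    "mixed_equilibria",
    "classify_stability",
    "tipping_point_K",
    "bifurcation_diagram",
    "sensitivity_scan",
]

#: residual tolerance (relative) accepted for a fixed point
_RESIDUAL_RTOL = 1e-9
#: margin excluding neutral numerical noise from the "stable" label
_STABILITY_MARGIN = 1e-9


@dataclasses.dataclass(frozen=True)
class FixedPoint:
    """A fixed point of the two-strategy map at territory count ``K``."""

    NA: float
    NF: float
    K: float
    stability: str  # "stable" | "unstable"
    eigenvalue_moduli: tuple[float, float]

    @property
    def f_aggressive(self) -> float:
        n = self.NA + self.NF
        return self.NA / n if n > 0 else float("nan")

    @property
    def n(self) -> float:
        return self.NA + self.NF


@dataclasses.dataclass
class BifurcationResult:
    """Equilibrium branches over a K grid plus the located fold.

    ``branches`` is a tidy DataFrame with columns
    ``K, area_km2, fA, NA, NF, stability, branch_id`` where branch_id is one
    of ``dove`` (fA=0), ``hawk`` (fA=1), ``mixed_low``, ``mixed_high``.
    ``K_star``/``area_star_km2`` hold the closed-form tipping point and
    ``K_star_numeric`` the fold located from the branches themselves.
    """

    branches: pd.DataFrame
    K_star: float
    area_star_km2: float
    K_star_numeric: float


def equilibrium_population(K: float, params: ModelParams) -> float:
    """Carrying capacity N* = b*K/mu of the single-strategy (dove) model."""
    if K < 0:
        raise ValueError("K must be >= 0")
    return params.b * K / params.mu


def breeding_fraction(params: ModelParams) -> float:
    """Fraction mu/b of the equilibrium population holding a territory.

    At carrying capacity only K of N* = b*K/mu birds breed, so the breeder
    fraction is mu/b and the remaining 1 - mu/b are floaters.
    """
    return params.mu / params.b


def _hawk_count_interior(params: ModelParams) -> float:
    """Hawk count at which injuries exactly balance recruitment: 1 + (b-mu)/(b*c)."""
    if params.c <= 0:
        raise ValueError("interior hawk equilibrium requires c > 0")
    return 1.0 + (params.b - params.mu) / (params.b * params.c)


def _residual(x: np.ndarray, K: float, params: ModelParams) -> np.ndarray:
    na2, nf2 = _step_raw(x[0], x[1], K, params)
    return np.array([na2 - x[0], nf2 - x[1]])


def _is_fixed_point(NA: float, NF: float, K: float, params: ModelParams) -> bool:
    na2, nf2 = _step_raw(NA, NF, K, params)
    scale = max(NA + NF, 1.0)
    return math.hypot(na2 - NA, nf2 - NF) < _RESIDUAL_RTOL * scale


def _jacobian(NA: float, NF: float, K: float, params: ModelParams) -> np.ndarray:
    """Finite-difference Jacobian of the map (central where possible).

    A one-sided difference is used when the central stencil would leave the
    admissible quadrant (e.g. at boundary equilibria with NA = 0).
    """
    x = np.array([NA, NF], dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        h = 1e-6 * max(abs(x[j]), 1.0)
        lo_ok = x[j] - h >= 0.0
        xp = x.copy()
        xp[j] += h
        fp = np.array(_step_raw(xp[0], xp[1], K, params))
        if lo_ok:
            xm = x.copy()
            xm[j] -= h
            fm = np.array(_step_raw(xm[0], xm[1], K, params))
            J[:, j] = (fp - fm) / (2.0 * h)
        else:
            f0 = np.array(_step_raw(x[0], x[1], K, params))
            J[:, j] = (fp - f0) / h
    return J


def classify_stability(NA: float, NF: float, K: float, params: ModelParams) -> tuple[str, tuple[float, float]]:
    """Stability of a fixed point from the Jacobian eigenvalue moduli.

    Stable iff all moduli are below 1 (with a small margin so that neutral
    numerical noise is not labelled stable).
    """
    if not _is_fixed_point(NA, NF, K, params):
        raise ValueError("point is not a fixed point of the map within tolerance")
    lam = np.linalg.eigvals(_jacobian(NA, NF, K, params))
    moduli = tuple(sorted(float(abs(v)) for v in lam))
    label = "stable" if moduli[-1] < 1.0 - _STABILITY_MARGIN else "unstable"
    return label, moduli


def _make_fp(NA: float, NF: float, K: float, params: ModelParams) -> FixedPoint:
    label, moduli = classify_stability(NA, NF, K, params)
    return FixedPoint(NA=NA, NF=NF, K=K, stability=label, eigenvalue_moduli=moduli)


def boundary_equilibria(K: float, params: ModelParams) -> tuple[FixedPoint, FixedPoint]:
    """The dove-only (fA=0) and hawk-only (fA=1) equilibria at territory count K.

    The dove equilibrium is the carrying capacity b*K/mu.  The hawk-only
    equilibrium is territory-limited (NA* = b*K/mu) for small K and
    injury-limited (NA* = 1 + (b-mu)/(b*c)) for large K; a bracketed root
    solve covers any parameter regime where neither analytic candidate
    self-consistently satisfies the one-strategy recursion.
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    nf_star = equilibrium_population(K, params)
    dove = _make_fp(0.0, nf_star, K, params)

    b, mu, c = params.b, params.mu, params.c
    na_star = None
    if c == 0.0:
        na_star = b * K / mu
    else:
        for cand in (b * K / mu, _hawk_count_interior(params)):
            w = min(cand, max(0.0, c * (cand - 1.0) * cand))
            if abs(b * max(0.0, min(K, cand - w)) - mu * cand) <= _RESIDUAL_RTOL * max(cand, 1.0):
                na_star = cand
                break
        if na_star is None:
            hi = 2.0 * max(b * K / mu, _hawk_count_interior(params), 1.0)
            na_star = optimize.brentq(
                lambda na: b * max(0.0, min(K, na - min(na, max(0.0, c * (na - 1.0) * na)))) - mu * na,
                1e-12,
                hi,
                xtol=1e-12,
            )
    hawk = _make_fp(float(na_star), 0.0, K, params)
    return dove, hawk


def mixed_equilibria(K: float, params: ModelParams) -> list[FixedPoint]:
    """Interior fixed points (0 < fA < 1) at territory count K.

    Found by Newton-type root-finding on the 2-D map itself from a coarse
    log grid of seeds.  The seed region follows from two properties of the
    map: an interior fixed point needs a positive hawk breeding pool, which
    bounds NA by the injury ceiling 1 + 1/c, and the dove count cannot
    exceed the dove-only carrying capacity b*K/mu.  Returns 0, 1 (exactly
    at the fold) or 2 points, sorted by increasing fA.  With c = 0 hawks
    dominate unconditionally and there is no interior equilibrium.
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    if params.c == 0.0:
        return []
    na_max = 1.0 + 1.0 / params.c
    nf_max = max(equilibrium_population(K, params), 10.0)
    # An interior fixed point pins the hawk count where injuries balance
    # recruitment (doves cannot be self-limited there since b > mu), so seed
    # densely around that count as well as over a generic log grid.
    na_balance = _hawk_count_interior(params)
    na_seeds = np.unique(np.concatenate([
        np.geomspace(2.0, 0.999 * na_max, 5),
        na_balance * np.array([0.95, 1.0, 1.05]),
    ]))
    nf_seeds = np.geomspace(2.0, nf_max, 10)
    found: list[tuple[float, float]] = []
    for na0 in na_seeds:
        for nf0 in nf_seeds:
            sol = optimize.root(
                _residual, np.array([na0, nf0]), args=(K, params), method="hybr", tol=1e-13
            )
            if not sol.success:
                continue
            na, nf = float(sol.x[0]), float(sol.x[1])
            if na <= 1e-6 or nf <= 1e-6:
                continue  # boundary equilibrium, not interior
            if not _is_fixed_point(na, nf, K, params):
                continue
            if any(math.hypot(na - a, nf - f) < 1e-6 * max(na + nf, 1.0) for a, f in found):
                continue
            found.append((na, nf))
    found.sort(key=lambda p: p[0] / (p[0] + p[1]))
    return [_make_fp(na, nf, K, params) for na, nf in found]


def tipping_point_K(params: ModelParams) -> tuple[float, float]:
    """Closed-form saddle-node location: critical territory count and island area.

    Solves (b*K/mu - 1)^2 - 4*(b*K/mu)*(1 + (b-mu)/(b*c)) = 0, a quadratic in
    x = b*K/mu, taking the larger root (the branch consistent with the fold
    of the interior equilibria).  Returns (K*, area* = K* * territory_km2).
    Without injuries (c = 0) hawks dominate at any island size and no finite
    tipping point exists.
    """
    if params.c <= 0:
        raise ValueError("no finite tipping point for c <= 0 (cost-free aggression dominates)")
    A = _hawk_count_interior(params)
    half = 1.0 + 2.0 * A  # x^2 - 2*half*x + 1 = 0
    x = half + math.sqrt(half * half - 1.0)
    k_star = x * params.mu / params.b
    return k_star, k_star * params.territory_km2


def _mixed_branch_gap(K: float, params: ModelParams) -> float | None:
    """Squared distance between the two mixed branches, or None if they are gone."""
    fps = mixed_equilibria(K, params)
    if len(fps) < 2:
        return None
    lo, hi = fps[0], fps[-1]
    return (lo.NA - hi.NA) ** 2 + (lo.NF - hi.NF) ** 2


def _locate_fold(K_lo: float, K_hi: float, params: ModelParams) -> float:
    """Numerically locate the fold in (K_lo, K_hi) by branch-distance minimisation.

    Bisects on the existence of interior equilibria, then fits a quadratic
    in K to the squared branch separation (which is polynomial in K near
    the fold, vanishing at it) and extrapolates to zero.
    """
    lo, hi = K_lo, K_hi
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if len(mixed_equilibria(mid, params)) == 0:
            lo = mid
        else:
            hi = mid
        if (hi - lo) <= 1e-6 * hi:
            break
    # refine: quadratic fit of gap^2 vs K just above the existence boundary
    ks, gaps = [], []
    for K in np.linspace(hi, hi + 0.05 * (K_hi - hi) + 1e-6 * hi, 6):
        g = _mixed_branch_gap(K, params)
        if g is not None:
            ks.append(K)
            gaps.append(g)
    if len(ks) >= 3:
        coef = np.polyfit(ks, gaps, 2)
        roots = np.roots(coef)
        real = [float(r.real) for r in roots if abs(r.imag) < 1e-8 * max(abs(r), 1.0)]
        cands = [r for r in real if K_lo <= r <= ks[-1]]
        if cands:
            return min(cands, key=lambda r: abs(r - hi))
    return 0.5 * (lo + hi)


def bifurcation_diagram(
    K_grid: np.ndarray,
    params: ModelParams,
    locate_fold: bool = True,
) -> BifurcationResult:
    """Trace all equilibrium branches of the map over a grid of territory counts.

    Produces the dove (fA=0), hawk (fA=1) and, where they exist, the two
    mixed branches, each with a stability label, plus the fold located
    numerically from the branches and the closed-form tipping point.
    """
    K_grid = np.sort(np.asarray(K_grid, dtype=float))
    if K_grid.size < 2:
        raise ValueError("K grid must contain at least two values")
    rows = []
    a_T = params.territory_km2
    had_mixed, lost_at, first_with = False, None, None
    for K in K_grid:
        dove, hawk = boundary_equilibria(K, params)
        for fp, bid in ((dove, "dove"), (hawk, "hawk")):
            rows.append((K, K * a_T, fp.f_aggressive, fp.NA, fp.NF, fp.stability, bid))
        mixed = mixed_equilibria(K, params)
        if len(mixed) == 2:
            had_mixed = True
            if first_with is None:
                first_with = K
            rows.append((K, K * a_T, mixed[0].f_aggressive, mixed[0].NA, mixed[0].NF, mixed[0].stability, "mixed_low"))
            rows.append((K, K * a_T, mixed[1].f_aggressive, mixed[1].NA, mixed[1].NF, mixed[1].stability, "mixed_high"))
        elif not had_mixed:
            lost_at = K
    branches = pd.DataFrame(rows, columns=["K", "area_km2", "fA", "NA", "NF", "stability", "branch_id"])

    if params.c > 0:
        k_star, area_star = tipping_point_K(params)
    else:
        k_star, area_star = float("nan"), float("nan")
    k_star_num = float("nan")
    if locate_fold and had_mixed and lost_at is not None and first_with is not None:
        k_star_num = _locate_fold(lost_at, first_with, params)
    return BifurcationResult(branches=branches, K_star=k_star, area_star_km2=area_star, K_star_numeric=k_star_num)


def sensitivity_scan(
    b_values,
    mu_values,
    c_values,
    params: ModelParams | None = None,
    rodrigues_range_km2: tuple[float, float] = (108.0, 1262.0),
    mauritius_range_km2: tuple[float, float] = (1852.0, 2958.0),
) -> pd.DataFrame:
    """Tipping-point island area over a grid of (b, mu, c) combinations.

    For each combination the closed-form tipping area is tabulated together
    with flags saying whether it falls inside configurable Rodrigues-like
    and Mauritius-like island-size fluctuation ranges (km²).  Combinations
    violating the viability constraint b > mu (or c <= 0) are kept in the
    table with a per-row diagnostic in the ``status`` column and NaN results.
    """
    base = params or ModelParams()
    rows = []
    for b in b_values:
        for mu in mu_values:
            for c in c_values:
                if not (0.0 < mu < b <= 1.0):
                    rows.append((b, mu, c, np.nan, np.nan, False, False, "invalid: requires 0 < mu < b <= 1"))
                    continue
                if c <= 0:
                    rows.append((b, mu, c, np.nan, np.nan, False, False, "invalid: requires c > 0"))
                    continue
                p = base.replace(b=b, mu=mu, c=c)
                k_star, area_star = tipping_point_K(p)
                rows.append(
                    (
                        b,
                        mu,
                        c,
                        k_star,
                        area_star,
                        rodrigues_range_km2[0] <= area_star <= rodrigues_range_km2[1],
                        mauritius_range_km2[0] <= area_star <= mauritius_range_km2[1],
                        "ok",
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["b", "mu", "c", "K_star", "area_star_km2", "in_rodrigues_range", "in_mauritius_range", "status"],
    )
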