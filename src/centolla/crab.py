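"""Slow layer: king-crab population dynamics under seasonal harvest.

The stock is a single dimensionless state ``x`` (fraction of the carrying
capacity ``x0``) obeying a cubic Allee-effect growth law with a harvest term
switched on only during the open part of each fishing year::

    dx/dt = x (1 - x) (x - lambda) - e * (x / x0) * I(t, sigma)

``lambda`` is the Allee threshold: an unfished stock below it declines to
extinction, above it recovers to the carrying capacity.  ``e`` is the
extraction rate relative to the reproduction rate of the crab, and
``I(t, sigma)`` indicates whether the season is open (the first fraction
``sigma`` of every year).

This module also carries the closed-form bifurcation analysis of the
constant-harvest system: the two non-trivial equilibria ``x±``, the
saddle-node critical extraction rate ``e*``, and the partition of the
``(e, x)`` plane into sustainable (I, II) and unsustainable (III, IV)
regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

#: Stock level below which the population is pinned to exactly zero
#: (extinction is absorbing; floating point must not undershoot).
EXTINCTION_EPS = 1e-9

#: Fraction of carrying capacity below which a run is reported as collapsed.
#: Well under a lambda = 0.1 Allee threshold, from which recovery is
#: impossible anyway; used for collapse-time reporting only.
COLLAPSE_FRACTION = 0.02

#: Output grid density of :func:`integrate_population` (points per year).
POINTS_PER_YEAR = 50


@dataclass(frozen=True)
class CrabParams:
    """Parameters of the stock dynamics.

    Parameters
    ----------
    lambda_allee
        Allee threshold as a population fraction, in (0, 1).
    x0
        Carrying capacity (normalised maximum population). The default 1
        makes ``x`` directly a fraction of the maximum.
    sigma
        Fraction of each year the fishery is open, in [0, 1].
    """

    lambda_allee: float = 0.1
    x0: float = 1.0
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_allee < 1.0:
            raise ValueError(
                f"lambda_allee must be in (0, 1), got {self.lambda_allee}"
            )
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must be in [0, 1], got {self.sigma}")
        if self.x0 <= 0.0:
            raise ValueError(f"x0 must be positive, got {self.x0}")


@dataclass(frozen=True)
class Trajectory:
    """Continuous population path on a strictly increasing time grid."""

    times: np.ndarray
    values: np.ndarray
    season_open: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "season_open", np.asarray(self.season_open, dtype=bool)
        )

    def first_crossing_below(self, level: float) -> float | None:
        """First time the population falls below ``level``.

        Linear interpolation between grid points; ``None`` if the path never
        crosses.
        """
        below = self.values < level
        if not below.any():
            return None
        i = int(np.argmax(below))
        if i == 0:
            return float(self.times[0])
        t0, t1 = self.times[i - 1], self.times[i]
        v0, v1 = self.values[i - 1], self.values[i]
        if v0 == v1:
            return float(t1)
        return float(t0 + (v0 - level) / (v0 - v1) * (t1 - t0))


@dataclass(frozen=True)
class EquilibriumSet:
    """Non-trivial fixed points of the constant-harvest stock equation.

    ``x_minus`` is unstable (the harvest-shifted Allee threshold),
    ``x_plus`` stable.  Both are NaN when ``exists`` is False, i.e. when the
    extraction rate exceeds the saddle-node value ``e*``.
    """

    x_minus: float
    x_plus: float
    exists: bool


class RegionLabel(str, Enum):
    """Bifurcation-diagram region of an ``(e, x)`` state.

    I and II are sustainable (the stock relaxes to ``x_plus``); III decays to
    extinction under constant harvest; IV has no equilibria at all
    (``e > e*``).
    """

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class RegimeLabel(str, Enum):
    """Stationary strategy composition of the fleet (from an all-super start)."""

    ALL_SUPER = "ALL_SUPER"
    MIXED_HALF = "MIXED_HALF"
    ALL_STANDARD = "ALL_STANDARD"


# ---------------------------------------------------------------------------
# Seasonal forcing
# ---------------------------------------------------------------------------

def fishing_indicator(t: float, sigma: float) -> int:
    """Season indicator: 1 while the fishery is open, 0 during the closure.

    Year ``k`` occupies ``[k, k+1)`` and its fishing window is ``[k, k+sigma)``,
    the closed-form value of the absolute-difference-of-step-functions forcing
    ``|H[sin(pi t)] - H[sin(pi (t - sigma))]|``.  For ``sigma = 0.5`` it
    coincides with the half-year forcing ``H[sin(2 pi t)]``.
    """
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"sigma must be in [0, 1], got {sigma}")
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if sigma == 1.0:
        return 1
    return 1 if (t - math.floor(t)) < sigma else 0


def fishing_indicator_heaviside(t: float, sigma: float) -> int:
    """Step-function form of the seasonal forcing.

    Direct evaluation of ``|H[sin(pi t)] - H[sin(pi (t - sigma))]|`` with
    ``H(y) = 1`` for ``y > 0``.  Equivalent to :func:`fishing_indicator` away
    from season boundaries; kept as the independent cross-check of that
    closed form.
    """
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"sigma must be in [0, 1], got {sigma}")
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if sigma == 1.0:
        return 1
    h1 = 1 if math.sin(math.pi * t) > 0 else 0
    h2 = 1 if math.sin(math.pi * (t - sigma)) > 0 else 0
    return abs(h1 - h2)


# ---------------------------------------------------------------------------
# Vector field and integration
# ---------------------------------------------------------------------------

def population_rhs(x: float, e: float, t: float, p: CrabParams) -> float:
    """Growth rate of the stock: Allee cubic minus the seasonal harvest term."""
    return x * (1.0 - x) * (x - p.lambda_allee) - e * (
        x / p.x0
    ) * fishing_indicator(t, p.sigma)


def _integrate_segment(
    x_start: float,
    t0: float,
    t1: float,
    e: float,
    p: CrabParams,
    n_points: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one smooth piece (harvest rate constant, no forcing switch)."""
    t_eval = np.linspace(t0, t1, n_points)
    if x_start <= EXTINCTION_EPS:
        return t_eval, np.zeros_like(t_eval)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        x = y[0]
        return [x * (1.0 - x) * (x - p.lambda_allee) - e * x / p.x0]

    sol = solve_ivp(
        rhs,
        (t0, t1),
        [x_start],
        method="RK45",
        t_eval=t_eval,
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - scipy failure is exceptional
        raise RuntimeError(
            f"stock integration failed on [{t0}, {t1}]: {sol.message}"
        )
    values = np.clip(sol.y[0], 0.0, None)
    dead = values < EXTINCTION_EPS
    if dead.any():
        values[int(np.argmax(dead)):] = 0.0
    return t_eval, values


def integrate_population(
    x_init: float,
    extraction_schedule: Sequence[float],
    years: int,
    p: CrabParams,
) -> Trajectory:
    """Integrate the stock over ``years`` with per-year extraction rates.

    The year-``k`` rate is held constant over year ``k``'s fishing window
    ``[k, k+sigma)``; the closure ``[k+sigma, k+1)`` is unfished.  Integration
    restarts at every season boundary — the forcing is discontinuous there and
    stepping across a switch biases collapse times.  Once the stock falls
    below ``EXTINCTION_EPS`` it is pinned to exactly zero.
    """
    if x_init < 0:
        raise ValueError(f"x_init must be non-negative, got {x_init}")
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    if len(extraction_schedule) < years:
        raise ValueError(
            f"schedule has {len(extraction_schedule)} entries for {years} years"
        )

    times: list[np.ndarray] = [np.array([0.0])]
    values: list[np.ndarray] = [np.array([float(x_init)])]
    x = float(x_init)
    for k in range(years):
        e_k = float(extraction_schedule[k])
        if e_k < 0:
            raise ValueError(f"extraction rate for year {k} is negative: {e_k}")
        segments = []
        if p.sigma > 0.0:
            segments.append((float(k), k + p.sigma, e_k))
        if p.sigma < 1.0:
            segments.append((k + p.sigma, float(k + 1), 0.0))
        for t0, t1, e_seg in segments:
            n_pts = max(2, int(round(POINTS_PER_YEAR * (t1 - t0))) + 1)
            seg_t, seg_x = _integrate_segment(x, t0, t1, e_seg, p, n_pts)
            x = float(seg_x[-1])
            times.append(seg_t[1:])  # drop duplicated boundary point
            values.append(seg_x[1:])

    t_all = np.concatenate(times)
    x_all = np.concatenate(values)
    season = np.array([bool(fishing_indicator(t, p.sigma)) for t in t_all])
    return Trajectory(times=t_all, values=x_all, season_open=season)


# ---------------------------------------------------------------------------
# Closed-form bifurcation analysis
# ---------------------------------------------------------------------------

def equilibria(e: float, lam: float) -> EquilibriumSet:
    """Non-trivial fixed points ``x±`` of the constant-harvest system.

    Roots of ``(1 - x)(x - lam) = e``:

        x± = (1 + lam)/2 ± (1/2) sqrt((1 + lam)^2 - 4 (lam + e))

    They satisfy the Vieta relations ``x- + x+ = 1 + lam`` and
    ``x- * x+ = lam + e``, and merge at the saddle-node when
    ``e = critical_extraction(lam)``.
    """
    if e < 0:
        raise ValueError(f"extraction rate must be non-negative, got {e}")
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lam must be in (0, 1), got {lam}")
    disc = (1.0 + lam) ** 2 - 4.0 * (lam + e)
    if disc < 0:
        return EquilibriumSet(x_minus=math.nan, x_plus=math.nan, exists=False)
    half_gap = 0.5 * math.sqrt(disc)
    mid = 0.5 * (1.0 + lam)
    return EquilibriumSet(x_minus=mid - half_gap, x_plus=mid + half_gap, exists=True)


def critical_extraction(lam: float) -> float:
    """Saddle-node extraction rate ``e* = (1 + lam)^2 / 4 - lam``.

    Above ``e*`` the harvested system has no equilibria and any stock level
    decays to extinction under year-round fishing.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lam must be in (0, 1), got {lam}")
    return 0.25 * (1.0 + lam) ** 2 - lam


def classify_region(e: float, x: float, lam: float) -> RegionLabel:
    """Place an ``(e, x)`` state in the bifurcation diagram.

    IV whenever ``e > e*`` (no equilibria, unconditional collapse under
    constant harvest); otherwise I strictly above the stable branch ``x+``,
    II between the branches, III at or below the unstable branch ``x-``.
    Boundary ties are resolved by the strict inequalities (``x = x+`` is II,
    ``x = x-`` is III) — measure zero, but deterministic.
    """
    if e < 0:
        raise ValueError(f"extraction rate must be non-negative, got {e}")
    if x < 0:
        raise ValueError(f"population must be non-negative, got {x}")
    if e > critical_extraction(lam):
        return RegionLabel.IV
    eq = equilibria(e, lam)
    if x > eq.x_plus:
        return RegionLabel.I
    if x > eq.x_minus:
        return RegionLabel.II
    return RegionLabel.III
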