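"""Coupled fast–slow dynamics: seasonal strategy play driving the stock.

One simulated year runs in three phases:

1. *decision phase* — every skipper, visited once in a fresh uniformly
   random order, evaluates the relative gain of the opposite strategy
   against the current neighbourhood and switches if the social thresholds
   allow; at most one switch per skipper per season;
2. *extraction* — the fleet's net extraction rate ``e_k`` is the sum of all
   per-vessel payoffs for the season;
3. *stock integration* — the crab population is integrated over the fishing
   window ``[k, k + sigma)`` with harvest rate ``e_k`` and over the closure
   ``[k + sigma, k + 1)`` unfished.

The stock enters the harvest term of the slow dynamics as ``e * x / x0``,
so extraction shrinks in proportion to what is left in the water.  By
default the seasonal payoffs themselves are evaluated at full stock
(``payoff_stock_coupling=False``): applying the stock factor a second time
inside the payoff matrix double-counts the dependence and understates the
extraction the model is meant to produce (see docs/methods.md).  Setting
``payoff_stock_coupling=True`` evaluates payoffs at the population left at
the end of the previous closure instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .crab import (
    COLLAPSE_FRACTION,
    POINTS_PER_YEAR,
    CrabParams,
    RegimeLabel,
    RegionLabel,
    Trajectory,
    _integrate_segment,
    classify_region,
    fishing_indicator,
)
from .decisions import SocialParams, decide_switch, relative_gain
from .network import (
    FisherNetwork,
    GameParams,
    NeighborhoodCounts,
    Strategy,
    build_er_network,
    total_extraction,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one coupled run.

    The defaults are the study conditions used throughout: 1000 vessels on a
    1000-link graph, share a = 0.64, illegal mean field psi = 0.3,
    interference gamma = 0.25, Allee threshold 0.1, half-year seasons,
    50 years, all-super start from full stock.
    """

    game: GameParams = field(default_factory=GameParams)
    crab: CrabParams = field(default_factory=CrabParams)
    social: SocialParams = field(default_factory=SocialParams)
    years: int = 50
    x_init: float = 1.0
    initial_strategy: Strategy = Strategy.SUPER
    seed: int = 0
    update_scheme: Literal["async", "synchronous"] = "async"
    payoff_stock_coupling: bool = False

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError(f"years must be >= 1, got {self.years}")
        if self.x_init < 0:
            raise ValueError(f"x_init must be >= 0, got {self.x_init}")
        if self.update_scheme not in ("async", "synchronous"):
            raise ValueError(
                f"update_scheme must be 'async' or 'synchronous', "
                f"got {self.update_scheme!r}"
            )


@dataclass(frozen=True)
class SeasonRecord:
    """Per-year bookkeeping of the coupled loop."""

    year: int
    e: float
    n_standard: int
    n_super: int
    x_start: float
    x_end_season: float
    x_end_year: float


@dataclass
class SimulationResult:
    seasons: list[SeasonRecord]
    trajectory: Trajectory | None
    network: FisherNetwork
    config: SimulationConfig
    final_regime: RegimeLabel
    collapsed: bool

    @property
    def final_x(self) -> float:
        """Stock at the end of the last year's closure."""
        return self.seasons[-1].x_end_year

    @property
    def final_e(self) -> float:
        return self.seasons[-1].e

    @property
    def final_n_standard(self) -> int:
        return self.seasons[-1].n_standard

    def standard_fraction_mean(self, last: int = 20) -> float:
        """Time-averaged standard-fisher fraction over the last seasons.

        The mixed regime alternates between all-super and all-standard
        seasons, so its composition is meaningful only as a time average.
        """
        recs = self.seasons[-last:]
        n = self.config.game.n
        return float(np.mean([r.n_standard / n for r in recs]))


def _update_strategies(
    net: FisherNetwork,
    gp: GameParams,
    social: SocialParams,
    x_payoff: float,
    rng: np.random.Generator,
    scheme: str,
) -> None:
    """One decision phase; mutates ``net.strategies`` in place.

    ``async``: skippers act in a fresh random order and see earlier switches
    immediately.  ``synchronous``: all decisions are taken on the frozen
    pre-season state and applied together.  Because the relative gain is
    neighbourhood-independent the two schemes produce the same composition;
    both are kept so that the equivalence can be checked rather than assumed.
    """
    order = rng.permutation(net.n_nodes)
    strategies = net.strategies
    if scheme == "synchronous":
        to_flip = []
        for i in order:
            k = _counts_of(net, int(i))
            g = relative_gain(Strategy(int(strategies[i])), k, gp, x_payoff)
            if decide_switch(g, social):
                to_flip.append(int(i))
        for i in to_flip:
            strategies[i] = 1 - strategies[i]
        return
    for i in order:
        i = int(i)
        k = _counts_of(net, i)
        g = relative_gain(Strategy(int(strategies[i])), k, gp, x_payoff)
        if decide_switch(g, social):
            strategies[i] = 1 - strategies[i]


def _counts_of(net: FisherNetwork, node: int) -> NeighborhoodCounts:
    nbrs = net.neighbors(node)
    k_d = int(net.strategies[nbrs].sum())
    return NeighborhoodCounts(k_c=len(nbrs) - k_d, k_d=k_d)


def _summarise_regime(fraction_standard: float) -> RegimeLabel:
    """Map a time-averaged standard fraction onto the nearest regime."""
    if fraction_standard < 0.25:
        return RegimeLabel.ALL_SUPER
    if fraction_standard > 0.75:
        return RegimeLabel.ALL_STANDARD
    return RegimeLabel.MIXED_HALF


def run(
    config: SimulationConfig,
    network: FisherNetwork | None = None,
    record_trajectory: bool = True,
) -> SimulationResult:
    """Run the coupled model for ``config.years`` seasons.

    Reproducibility: the graph and the per-season visiting orders are drawn
    from independent streams spawned from ``config.seed``, so identical
    configs give bit-identical season records.  A caller-supplied ``network``
    (e.g. an observed fleet) bypasses the graph draw but keeps the rest of
    the seeding intact.
    """
    ss = np.random.SeedSequence(config.seed)
    graph_rng, order_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    gp, crab, social = config.game, config.crab, config.social
    if network is None:
        net = build_er_network(gp.n, gp.m_links, graph_rng, config.initial_strategy)
    else:
        net = network

    seasons: list[SeasonRecord] = []
    times = [np.array([0.0])]
    values = [np.array([float(config.x_init)])]
    x = float(config.x_init)
    collapse_level = COLLAPSE_FRACTION * crab.x0
    collapsed = False
    x_prev_closure = x  # stock at the end of the previous closure
    for k in range(config.years):
        x_payoff = x_prev_closure if config.payoff_stock_coupling else crab.x0
        _update_strategies(net, gp, social, x_payoff, order_rng, config.update_scheme)
        e_k = total_extraction(net, gp, x_payoff)
        n_super = int(net.strategies.sum())
        x_start = x

        segments = []
        if crab.sigma > 0.0:
            segments.append((float(k), k + crab.sigma, e_k))
        if crab.sigma < 1.0:
            segments.append((k + crab.sigma, float(k + 1), 0.0))
        x_end_season = x
        for si, (t0, t1, e_seg) in enumerate(segments):
            n_pts = max(2, int(round(POINTS_PER_YEAR * (t1 - t0))) + 1)
            seg_t, seg_x = _integrate_segment(x, t0, t1, e_seg, crab, n_pts)
            x = float(seg_x[-1])
            if seg_x.min() < collapse_level:
                collapsed = True
            if si == 0 and crab.sigma > 0.0:
                x_end_season = x
            if record_trajectory:
                times.append(seg_t[1:])
                values.append(seg_x[1:])
        if crab.sigma == 0.0:
            x_end_season = x_start
        x_prev_closure = x

        seasons.append(
            SeasonRecord(
                year=k,
                e=e_k,
                n_standard=gp.n - n_super,
                n_super=n_super,
                x_start=x_start,
                x_end_season=x_end_season,
                x_end_year=x,
            )
        )

    trajectory = None
    if record_trajectory:
        t_all = np.concatenate(times)
        x_all = np.concatenate(values)
        season_open = np.array(
            [bool(fishing_indicator(t, crab.sigma)) for t in t_all]
        )
        trajectory = Trajectory(times=t_all, values=x_all, season_open=season_open)

    n = gp.n
    frac = float(np.mean([r.n_standard / n for r in seasons[-min(20, len(seasons)):]]))
    return SimulationResult(
        seasons=seasons,
        trajectory=trajectory,
        network=net,
        config=config,
        final_regime=_summarise_regime(frac),
        collapsed=collapsed,
    )


# ---------------------------------------------------------------------------
# Scenario sweeps
# ---------------------------------------------------------------------------

def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def sweep_share(
    a_grid: Sequence[float],
    n_runs: int,
    base_config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Monte-Carlo sweep over the share parameter with random social thresholds.

    For every value of ``a``, ``n_runs`` independent runs are made; each
    resamples the graph (through a fresh seed) and the social parameters
    (atsf ~ U(0, 1), social_pressure ~ U(-1, 0)).  Year-50 summaries are
    returned as a tidy frame.
    """
    rows = []
    for a in a_grid:
        if a < 0:
            raise ValueError(f"share parameter must be non-negative, got {a}")
        for _ in range(n_runs):
            social = SocialParams(
                atsf=float(rng.uniform(0.0, 1.0)),
                social_pressure=float(-rng.uniform(0.0, 1.0)),
            )
            cfg = replace(
                base_config,
                game=replace(base_config.game, a=float(a)),
                social=social,
                seed=_spawn_seed(rng),
            )
            res = run(cfg, record_trajectory=False)
            rows.append(
                {
                    "a": float(a),
                    "atsf": social.atsf,
                    "social_pressure": social.social_pressure,
                    "final_x": res.final_x,
                    "final_e": res.final_e,
                    "final_n_standard": res.final_n_standard,
                    "mean_standard_fraction": res.standard_fraction_mean(),
                    "collapsed": res.collapsed,
                }
            )
    return pd.DataFrame(rows)


def sweep_share_sigma(
    a_grid: Sequence[float],
    sigma_grid: Sequence[float],
    runs_per_cell: int,
    base_config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Year-50 stock over a (share, season-length) grid.

    Social thresholds are held at ``base_config.social`` (the graph is still
    resampled per run), so the grid isolates the joint harvest pressure of
    ``a`` and ``sigma``.
    """
    rows = []
    for sigma in sigma_grid:
        for a in a_grid:
            for r in range(runs_per_cell):
                cfg = replace(
                    base_config,
                    game=replace(base_config.game, a=float(a)),
                    crab=replace(base_config.crab, sigma=float(sigma)),
                    seed=_spawn_seed(rng),
                )
                res = run(cfg, record_trajectory=False)
                rows.append(
                    {
                        "a": float(a),
                        "sigma": float(sigma),
                        "run": r,
                        "final_x": res.final_x,
                        "final_e": res.final_e,
                        "final_n_standard": res.final_n_standard,
                        "collapsed": res.collapsed,
                    }
                )
    return pd.DataFrame(rows)


def bifurcation_projection(results: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Project sweep outcomes onto the constant-harvest bifurcation diagram.

    Pairs each run's year-50 ``(e, x)`` with its region label; survivors in
    region IV are the signature of the seasonal-closure rescue, where the
    stock recovers during closures at extraction rates that would be
    unsustainable year-round.
    """
    out = results[["final_e", "final_x"]].copy()
    out["region"] = [
        classify_region(float(e), float(x), lam)
        for e, x in zip(out["final_e"], out["final_x"])
    ]
    return out
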