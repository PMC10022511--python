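"""Fast layer: the fleet of registered vessels and its payoff structure.

Registered vessels are nodes of a sparse Erdős–Rényi graph; an edge means
two vessels compete for the crab at the same grounds.  Each vessel plays one
of two strategies: a *standard* fisher ignores the illegal (unregistered)
fleet, a *super* fisher whitewashes its catch for a ``(1 + psi)`` payoff
premium, where ``psi`` is the mean-field intensity of unregistered vessels.

The per-vessel payoff is the multiplayer Prisoner's-Dilemma matrix

    c(k_c, k_d) = (a/n) * x / (1 + [k_c + (1 + psi * k_d)]^gamma)
    d(k_c, k_d) = (1 + psi) * c(k_c, k_d)

with ``k_c`` / ``k_d`` the standard / super neighbours of the vessel,
``a`` the share parameter (net extraction rate of a non-competing
all-standard fleet), ``gamma`` the interference exponent and ``x`` the crab
stock the payoff is evaluated at.  The fleet's net extraction rate is the
sum of all ``n`` payoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class Strategy(IntEnum):
    STANDARD = 0
    SUPER = 1


@dataclass(frozen=True)
class GameParams:
    """Parameters of the extraction game.

    ``a`` is what an all-standard, interference-free fleet would extract in
    total; ``psi`` both scales the illegal mean field and equals the exact
    relative temptation to defect; ``gamma`` in [0, 1] controls how
    co-located competitors depress each other's payoff (0 = none, 1 = the
    whole group extracts like a single vessel).
    """

    n: int = 1000
    a: float = 0.64
    psi: float = 0.3
    gamma: float = 0.25
    m_links: int = 1000

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.a < 0:
            raise ValueError(f"a must be non-negative, got {self.a}")
        if self.psi < 0:
            raise ValueError(f"psi must be non-negative, got {self.psi}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        max_links = self.n * (self.n - 1) // 2
        if not 0 <= self.m_links <= max_links:
            raise ValueError(
                f"m_links must be in [0, {max_links}] for n={self.n}, "
                f"got {self.m_links}"
            )


@dataclass(frozen=True)
class NeighborhoodCounts:
    """Strategy census of one vessel's competitors."""

    k_c: int
    k_d: int


@dataclass
class FisherNetwork:
    """Simple undirected competition graph with a per-node strategy label."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int array, u < v, unique
    strategies: np.ndarray  # (n,) int8 of Strategy values
    # adjacency lists, built lazily; index i -> int array of neighbours
    _neighbors: list[np.ndarray] | None = field(default=None, repr=False)

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: Iterable[tuple[int, int]],
        strategies: Strategy | Sequence[int] = Strategy.SUPER,
    ) -> "FisherNetwork":
        """Build a network from an explicit edge list.

        ``strategies`` may be a single label applied to every node or a
        length-``n`` sequence.
        """
        edge_arr = np.array(sorted({tuple(sorted(e)) for e in edges}), dtype=np.int64)
        if edge_arr.size == 0:
            edge_arr = np.empty((0, 2), dtype=np.int64)
        else:
            if edge_arr.min() < 0 or edge_arr.max() >= n_nodes:
                raise ValueError("edge endpoint out of range")
            if (edge_arr[:, 0] == edge_arr[:, 1]).any():
                raise ValueError("self-loops are not allowed")
        if isinstance(strategies, Strategy):
            strat = np.full(n_nodes, int(strategies), dtype=np.int8)
        else:
            strat = np.asarray(strategies, dtype=np.int8)
            if strat.shape != (n_nodes,):
                raise ValueError("strategy vector length must equal n_nodes")
            if not np.isin(strat, (0, 1)).all():
                raise ValueError("strategies must be STANDARD (0) or SUPER (1)")
        return cls(n_nodes=n_nodes, edges=edge_arr, strategies=strat)

    @property
    def m_links(self) -> int:
        return int(self.edges.shape[0])

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.m_links:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def neighbors(self, node: int) -> np.ndarray:
        if self._neighbors is None:
            adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for u, v in self.edges:
                adj[u].append(int(v))
                adj[v].append(int(u))
            self._neighbors = [np.array(a, dtype=np.int64) for a in adj]
        return self._neighbors[node]

    def super_neighbor_counts(self) -> np.ndarray:
        """Vector of ``k_d`` (super neighbours) for every node."""
        k_d = np.zeros(self.n_nodes, dtype=np.int64)
        if self.m_links:
            s = self.strategies
            np.add.at(k_d, self.edges[:, 0], s[self.edges[:, 1]])
            np.add.at(k_d, self.edges[:, 1], s[self.edges[:, 0]])
        return k_d

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        nx.set_node_attributes(
            g, {i: Strategy(int(s)).name for i, s in enumerate(self.strategies)},
            "strategy",
        )
        return g


def build_er_network(
    n: int,
    m_links: int,
    rng: np.random.Generator,
    initial_strategy: Strategy = Strategy.SUPER,
) -> FisherNetwork:
    """Uniform random simple graph with exactly ``m_links`` edges (G(n, M)).

    The default ``m = n`` at ``n = 1000`` gives mean degree exactly 2: every
    vessel competes with two others on average, reflecting how sparsely the
    fleet is spread over the fishing grounds.  Strategies start uniform, by
    default all super (the worst case).
    """
    if m_links > n * (n - 1) // 2:
        raise ValueError(
            f"cannot place {m_links} edges on {n} nodes without multi-edges"
        )
    g = nx.gnm_random_graph(n, m_links, seed=rng)
    return FisherNetwork.from_edges(n, g.edges(), initial_strategy)


def neighborhood_counts(net: FisherNetwork, node: int) -> NeighborhoodCounts:
    """Count a vessel's standard and super competitors."""
    if not 0 <= node < net.n_nodes:
        raise KeyError(f"node {node} not in network of {net.n_nodes} nodes")
    nbrs = net.neighbors(node)
    k_d = int(net.strategies[nbrs].sum())
    return NeighborhoodCounts(k_c=len(nbrs) - k_d, k_d=k_d)


def payoff(
    strategy: Strategy,
    k: NeighborhoodCounts,
    gp: GameParams,
    x_prev: float,
) -> float:
    """Seasonal payoff of one vessel given its competitors' strategies.

    The super payoff is exactly ``(1 + psi)`` times the standard payoff at
    equal arguments — the identity behind the fleet's constant relative
    temptation.
    """
    if x_prev < 0:
        raise ValueError(f"population must be non-negative, got {x_prev}")
    bracket = k.k_c + 1.0 + gp.psi * k.k_d
    base = (gp.a / gp.n) * x_prev / (1.0 + bracket**gp.gamma)
    if strategy == Strategy.SUPER:
        return (1.0 + gp.psi) * base
    return base


def total_extraction(net: FisherNetwork, gp: GameParams, x_prev: float) -> float:
    """Net extraction rate of the fleet: the sum of all per-vessel payoffs."""
    if x_prev < 0:
        raise ValueError(f"population must be non-negative, got {x_prev}")
    k_d = net.super_neighbor_counts()
    k_c = net.degrees() - k_d
    bracket = k_c + 1.0 + gp.psi * k_d
    per = (gp.a / gp.n) * x_prev / (1.0 + bracket**gp.gamma)
    per = np.where(net.strategies == Strategy.SUPER, (1.0 + gp.psi) * per, per)
    return float(per.sum())


def poisson_mixture_extraction(
    gp: GameParams,
    strategy: Strategy,
    x_prev: float = 1.0,
    k_max: int = 80,
) -> float:
    """Degree-mixture approximation of the uniform-fleet extraction rate.

    For a G(n, M) graph with mean degree ``2 m / n`` the degree distribution
    is asymptotically Poisson; with every vessel playing ``strategy`` the
    expected fleet extraction is the Poisson mixture of the per-degree
    payoff.  Used as an analytic cross-check of :func:`total_extraction`
    ensembles.
    """
    from scipy.stats import poisson

    mean_deg = 2.0 * gp.m_links / gp.n
    mult = (1.0 + gp.psi) if strategy == Strategy.SUPER else 1.0
    ks = np.arange(k_max + 1)
    pmf = poisson.pmf(ks, mean_deg)
    if strategy == Strategy.SUPER:
        bracket = 1.0 + gp.psi * ks
    else:
        bracket = ks + 1.0
    per = mult * (gp.a / gp.n) * x_prev / (1.0 + bracket**gp.gamma)
    return float(gp.n * np.sum(pmf * per))


def mean_total_profit_sweep(
    gamma_grid: Sequence[float],
    psi_list: Sequence[float],
    strategy_config: Strategy,
    n_reps: int,
    gp: GameParams,
    rng: np.random.Generator,
    x_prev: float = 1.0,
) -> pd.DataFrame:
    """Mean fleet profit versus interference for a frozen strategy profile.

    For each ``(gamma, psi)`` pair, ``n_reps`` independent graph realisations
    are drawn and the fleet extraction evaluated one-shot (no decision
    dynamics).  Returns a tidy frame with columns gamma, psi, mean, sd.
    """
    rows = []
    for psi in psi_list:
        for gamma in gamma_grid:
            gp_cell = GameParams(
                n=gp.n, a=gp.a, psi=float(psi), gamma=float(gamma),
                m_links=gp.m_links,
            )
            vals = np.empty(n_reps)
            for r in range(n_reps):
                net = build_er_network(
                    gp_cell.n, gp_cell.m_links, rng, strategy_config
                )
                vals[r] = total_extraction(net, gp_cell, x_prev)
            rows.append(
                {
                    "gamma": float(gamma),
                    "psi": float(psi),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if n_reps > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
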