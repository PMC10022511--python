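"""Configuration files, run manifests and artifact writers.

Configs are flat YAML key-value files; every key is optional and defaults
to the study conditions (n=1000, m_links=1000, psi=0.3, gamma=0.25,
lambda_allee=0.1, sigma=0.5, years=50, all-super start from full stock).
Outputs are plain text: season records and trajectories as CSV (fixed
column order, ``%.10g`` floats), summaries and manifests as JSON, the
network as a whitespace-delimited edge list plus a per-node strategy CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from datetime import datetime, timezone
from importlib import metadata
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .crab import CrabParams
from .decisions import SocialParams
from .network import FisherNetwork, GameParams, Strategy
from .simulate import SimulationConfig, SimulationResult

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"

#: YAML key -> (dataclass section, field name); flat on purpose so a config
#: reads like the parameter table of the model.
_KEYMAP: dict[str, tuple[str | None, str]] = {
    "n": ("game", "n"),
    "a": ("game", "a"),
    "psi": ("game", "psi"),
    "gamma": ("game", "gamma"),
    "m_links": ("game", "m_links"),
    "lambda_allee": ("crab", "lambda_allee"),
    "x0": ("crab", "x0"),
    "sigma": ("crab", "sigma"),
    "atsf": ("social", "atsf"),
    "social_pressure": ("social", "social_pressure"),
    "years": (None, "years"),
    "x_init": (None, "x_init"),
    "initial_strategy": (None, "initial_strategy"),
    "seed": (None, "seed"),
    "update_scheme": (None, "update_scheme"),
    "payoff_stock_coupling": (None, "payoff_stock_coupling"),
}


class ConfigError(ValueError):
    """Raised with every violation found in a config file, not just the first."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems)
        )


def load_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a YAML config, applying defaults for omitted keys."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    problems = [f"unknown key {k!r}" for k in raw if k not in _KEYMAP]

    sections: dict[str | None, dict[str, Any]] = {"game": {}, "crab": {}, "social": {}, None: {}}
    for key, value in raw.items():
        if key not in _KEYMAP:
            continue
        section, name = _KEYMAP[key]
        if key == "initial_strategy":
            try:
                value = Strategy[str(value).upper()]
            except KeyError:
                problems.append(
                    f"initial_strategy must be 'standard' or 'super', got {value!r}"
                )
                continue
        sections[section][name] = value

    cfg = None
    if not problems:
        try:
            cfg = SimulationConfig(
                game=GameParams(**sections["game"]),
                crab=CrabParams(**sections["crab"]),
                social=SocialParams(**sections["social"]),
                **sections[None],
            )
        except (TypeError, ValueError) as exc:
            problems.append(str(exc))
    if problems:
        raise ConfigError(problems)
    assert cfg is not None
    return cfg


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as flat YAML; ``load_config`` round-trips it exactly."""
    flat: dict[str, Any] = {}
    for key, (section, name) in _KEYMAP.items():
        obj = {
            "game": config.game,
            "crab": config.crab,
            "social": config.social,
            None: config,
        }[section]
        value = getattr(obj, name)
        if isinstance(value, Strategy):
            value = value.name.lower()
        flat[key] = value
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))


def _package_version() -> str:
    try:
        return metadata.version("centolla")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    config: dict[str, Any]
    master_seed: int
    derived_seeds: dict[str, str]
    version: str
    created: str

    @classmethod
    def for_config(cls, config: SimulationConfig) -> "RunManifest":
        ss = np.random.SeedSequence(config.seed)
        graph_ss, order_ss = ss.spawn(2)
        cfg_dict = dataclasses.asdict(config)
        cfg_dict["initial_strategy"] = config.initial_strategy.name
        return cls(
            config=cfg_dict,
            master_seed=config.seed,
            derived_seeds={
                "graph": f"SeedSequence({graph_ss.entropy}, spawn_key={graph_ss.spawn_key})",
                "update_order": f"SeedSequence({order_ss.entropy}, spawn_key={order_ss.spawn_key})",
            },
            version=_package_version(),
            created=datetime.now(timezone.utc).isoformat(),
        )


def write_network(net: FisherNetwork, outdir: Path) -> None:
    edge_lines = "".join(f"{u} {v}\n" for u, v in net.edges)
    (outdir / "network_edges.txt").write_text(edge_lines)
    strat = pd.DataFrame(
        {
            "node_id": np.arange(net.n_nodes),
            "strategy": [Strategy(int(s)).name for s in net.strategies],
        }
    )
    strat.to_csv(outdir / "strategies.csv", index=False)


def read_edge_list(path: str | Path, n_nodes: int) -> FisherNetwork:
    """Load a user-supplied fleet as 0-based whitespace-delimited node pairs."""
    pairs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected two node ids, got {line!r}")
        pairs.append((int(parts[0]), int(parts[1])))
    return FisherNetwork.from_edges(n_nodes, pairs)


def write_outputs(result: SimulationResult, outdir: str | Path) -> list[Path]:
    """Write all artifacts of one run; returns the paths written.

    Files: seasons.csv (one row per season), trajectory.csv, summary.json,
    manifest.json, network_edges.txt, strategies.csv.  Re-running with the
    same config yields byte-identical CSVs.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        seasons = pd.DataFrame([dataclasses.asdict(s) for s in result.seasons])
        seasons = seasons[
            ["year", "e", "n_standard", "n_super", "x_start",
             "x_end_season", "x_end_year"]
        ]
        seasons.to_csv(outdir / "seasons.csv", index=False, float_format=FLOAT_FORMAT)

        if result.trajectory is not None:
            traj = pd.DataFrame(
                {
                    "time_years": result.trajectory.times,
                    "population": result.trajectory.values,
                    "season_open": result.trajectory.season_open.astype(int),
                }
            )
            traj.to_csv(
                outdir / "trajectory.csv", index=False, float_format=FLOAT_FORMAT
            )

        summary = {
            "final_x": result.final_x,
            "final_e": result.final_e,
            "final_n_standard": result.final_n_standard,
            "mean_standard_fraction_last20": result.standard_fraction_mean(),
            "final_regime": result.final_regime.value,
            "collapsed": result.collapsed,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

        manifest = RunManifest.for_config(result.config)
        (outdir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2) + "\n"
        )
        write_network(result.network, outdir)
    except OSError as exc:
        raise OSError(f"writing outputs under {outdir}: {exc}") from exc
    written = ["seasons.csv", "summary.json", "manifest.json",
               "network_edges.txt", "strategies.csv"]
    if result.trajectory is not None:
        written.insert(1, "trajectory.csv")
    return [outdir / name for name in written]
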