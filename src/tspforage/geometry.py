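"""Arena/target geometry: configurations, strategy taxonomy, distances.

Coordinate convention: the arena is a circle centred at the origin, axes in
centimetres, y increasing "up".  Targets are flat discs on the floor and are
treated as points.  Each configuration carries a route-selection strategy
category describing which heuristic produces (or fails to produce) the
optimal route for that layout:

* ``BASELINE`` — four-target warm-up layouts, too small to dissociate
  strategies (configurations 1 and 2);
* ``L_P`` — local-perimeter ("hull") layouts: walking the arena perimeter
  first and then the interior is optimal (configurations 3 and 6);
* ``L_NN`` — local-nearest-neighbour layouts: greedy transitions to the
  closest remaining target are optimal (configurations 4 and 7);
* ``GLOBAL`` — layouts where both local heuristics are suboptimal and only
  whole-configuration planning finds the shortest route (configurations 5
  and 8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Strategy",
    "ArenaConfig",
    "DistanceMatrix",
    "STRATEGY_BY_CONFIG_ID",
    "load_configurations",
    "write_configurations",
    "distance_matrix",
    "bundled_configurations",
]


class Strategy(str, Enum):
    """Route-selection strategy category of a target configuration."""

    BASELINE = "BASELINE"
    L_P = "L_P"
    L_NN = "L_NN"
    GLOBAL = "GLOBAL"


#: Default mapping from configuration id to strategy category.
STRATEGY_BY_CONFIG_ID: dict[int, Strategy] = {
    1: Strategy.BASELINE,
    2: Strategy.BASELINE,
    3: Strategy.L_P,
    6: Strategy.L_P,
    4: Strategy.L_NN,
    7: Strategy.L_NN,
    5: Strategy.GLOBAL,
    8: Strategy.GLOBAL,
}


class ConfigError(ValueError):
    """Raised for malformed or geometrically invalid configurations."""


@dataclass(frozen=True)
class ArenaConfig:
    """One target configuration inside a circular arena.

    Parameters
    ----------
    config_id
        Small integer identifying the configuration.
    targets
        Ordered ``(target_id, x_cm, y_cm)`` triples, arena centre at origin.
    strategy
        Strategy category label.
    arena_diameter
        Arena diameter in cm (the standard arena is 100 cm).
    """

    config_id: int
    targets: tuple[tuple[int, float, float], ...]
    strategy: Strategy
    arena_diameter: float = 100.0

    def __post_init__(self) -> None:
        if len(self.targets) < 2:
            raise ConfigError(
                f"config {self.config_id}: needs >=2 targets, got {len(self.targets)}"
            )
        ids = [t[0] for t in self.targets]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"config {self.config_id}: duplicate target ids {ids}")
        r2 = (self.arena_diameter / 2.0) ** 2
        for tid, x, y in self.targets:
            if x * x + y * y >= r2:
                raise ConfigError(
                    f"config {self.config_id}: target {tid} at ({x}, {y}) lies "
                    f"outside the arena (diameter {self.arena_diameter} cm)"
                )
        if self.strategy is Strategy.BASELINE and len(self.targets) != 4:
            raise ConfigError(
                f"config {self.config_id}: baseline configurations have exactly "
                f"4 targets, got {len(self.targets)}"
            )

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def target_ids(self) -> tuple[int, ...]:
        return tuple(t[0] for t in self.targets)

    def coordinates(self) -> np.ndarray:
        """``(n, 2)`` array of target coordinates in listed order."""
        return np.array([[x, y] for _, x, y in self.targets], dtype=float)

    def index_of(self, target_id: int) -> int:
        try:
            return self.target_ids.index(target_id)
        except ValueError:
            raise KeyError(f"config {self.config_id}: unknown target id {target_id}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Euclidean inter-target distances (cm) for one configuration."""

    target_ids: tuple[int, ...]
    d: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.target_ids)

    def between(self, tid_a: int, tid_b: int) -> float:
        ia = self.target_ids.index(tid_a)
        ib = self.target_ids.index(tid_b)
        return float(self.d[ia, ib])


def distance_matrix(config: ArenaConfig) -> DistanceMatrix:
    """Pairwise Euclidean distance matrix of a configuration's targets.

    Raises
    ------
    ConfigError
        If two targets coincide (zero off-diagonal distance).
    """
    xy = config.coordinates()
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    off = d[~np.eye(len(xy), dtype=bool)]
    if off.size and off.min() <= 0.0:
        raise ConfigError(f"config {config.config_id}: coincident targets")
    return DistanceMatrix(target_ids=config.target_ids, d=d)


def _strategy_from_value(value, config_id: int) -> Strategy:
    if isinstance(value, Strategy):
        return value
    if value is None:
        try:
            return STRATEGY_BY_CONFIG_ID[config_id]
        except KeyError:
            raise ConfigError(
                f"config {config_id}: no strategy given and id not in the "
                f"default 8-configuration mapping"
            )
    try:
        return Strategy(str(value).upper().replace("-", "_"))
    except ValueError:
        raise ConfigError(f"config {config_id}: unknown strategy {value!r}")


def load_configurations(path: str | Path) -> list[ArenaConfig]:
    """Load configurations from JSON or a delimited table.

    JSON layout: one document with ``arena_diameter_cm`` and ``configs``,
    each config ``{id, strategy, targets: [{id, x, y}]}``.  The delimited
    dialect has columns ``config_id, target_id, x_cm, y_cm`` (strategy
    assigned from the default id mapping).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _load_json(path)
    return _load_table(path)


def _load_json(path: Path) -> list[ArenaConfig]:
    with open(path) as fh:
        doc = json.load(fh)
    diameter = float(doc.get("arena_diameter_cm", 100.0))
    configs: list[ArenaConfig] = []
    seen: set[int] = set()
    for entry in doc["configs"]:
        cid = int(entry["id"])
        if cid in seen:
            raise ConfigError(f"duplicate config_id {cid} in {path}")
        seen.add(cid)
        targets = tuple(
            (int(t["id"]), float(t["x"]), float(t["y"])) for t in entry["targets"]
        )
        strategy = _strategy_from_value(entry.get("strategy"), cid)
        configs.append(
            ArenaConfig(
                config_id=cid,
                targets=targets,
                strategy=strategy,
                arena_diameter=diameter,
            )
        )
    return configs


def _load_table(path: Path) -> list[ArenaConfig]:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    required = {"config_id", "target_id", "x_cm", "y_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x_cm", "y_cm"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header row, one for 0-based indexing
            raise ConfigError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
    configs = []
    for cid, sub in df.groupby("config_id", sort=True):
        targets = tuple(
            (int(r.target_id), float(r.x_cm), float(r.y_cm))
            for r in sub.itertuples()
        )
        configs.append(
            ArenaConfig(
                config_id=int(cid),
                targets=targets,
                strategy=_strategy_from_value(None, int(cid)),
            )
        )
    return configs


def write_configurations(configs: Iterable[ArenaConfig], path: str | Path) -> None:
    """Write configurations to JSON (round-trips ``load_configurations``)."""
    configs = list(configs)
    diameters = {c.arena_diameter for c in configs}
    if len(diameters) > 1:
        raise ConfigError("all configurations in one file must share a diameter")
    doc = {
        "arena_diameter_cm": configs[0].arena_diameter if configs else 100.0,
        "coordinate_convention": "arena centre at origin, cm, y up",
        "configs": [
            {
                "id": c.config_id,
                "strategy": c.strategy.value,
                "targets": [
                    {"id": tid, "x": x, "y": y} for tid, x, y in c.targets
                ],
            }
            for c in configs
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def bundled_configurations() -> list[ArenaConfig]:
    """The eight reconstructed study-style configurations shipped in-package.

    The published layouts give only the design rules (perimeter-heavy for
    L-P, partially interior for L-NN, heuristic-defeating for GLOBAL); these
    coordinates are reconstructions obeying those rules, verified against
    the exact solver, not digitised originals.
    """
    ref = resources.files("tspforage.data") / "configurations.json"
    with resources.as_file(ref) as p:
        return load_configurations(p)
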