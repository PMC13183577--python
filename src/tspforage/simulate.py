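"""Synthetic foraging cohorts and microglia shape populations.

Everything the scoring pipeline consumes can be generated here with known
ground truth: trial event logs with matching position tracks, full
strain x sex cohorts, and labelled microglia masks.

Foraging agent
--------------
An agent starts at a random point on the arena wall and repeatedly picks a
next target.  At each step it samples one of four route-selection policies
(OPTIMAL: follow a fixed optimal route; NN: nearest remaining target;
HULL: follow the perimeter-first route; RANDOM: uniform), then picks among
candidate targets by a softmax over the policy's preference ranks —
``P(target) ∝ exp(-rank / temperature)`` — so ``temperature`` is a
continuous adherence dial with the deterministic policy recovered at 0.
On first contact with a baited target the agent fails to retrieve with
probability ``p_skip`` (retrieving on a later pass).  Two memory-error
channels produce revisits: a sliding window over the ``memory_capacity``
most recently depleted targets (older depleted targets are forgotten and
re-enter the candidate set, so revisit pressure grows with target count),
and a per-step lapse rate ``p_lapse`` under which a uniformly drawn
depleted target is momentarily believed baited and visited regardless of
the route policy.  The lapse channel is what the default cohort design
uses, because it makes the revisit process independent of route-selection
adherence — an impaired-route-selection, intact-memory configuration.  Travel runs at a per-trial speed drawn from a truncated
normal, and a straight-segment position track is emitted at a fixed
sample rate.

The default cohort design encodes the reference conditions: 2 strains x
2 sexes x 9 rats per cell, eight configurations, an ADHD-model (SHR)
deficit in optimal-route adherence and elevated speed, a male excess in
skip probability, and identical memory in all cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import ArenaConfig, Strategy, distance_matrix
from .measures import EventKind, TrialLog
from .morphology import MorphClass
from .routes import (
    OptimalRouteSet,
    hull_perimeter_route,
    optimal_route,
)

__all__ = [
    "AgentParams",
    "CohortDesign",
    "SimulatedCohort",
    "simulate_trial",
    "simulate_cohort",
    "simulate_microglia",
    "make_cell_mask",
    "default_design",
]

TRACK_HZ = 10.0
STEP_CAP_PER_TARGET = 60

POLICIES = ("OPTIMAL", "NN", "HULL", "RANDOM")


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of one simulated rat."""

    strategy_weights: dict[str, float] = field(
        default_factory=lambda: {"OPTIMAL": 0.25, "NN": 0.25,
                                 "HULL": 0.25, "RANDOM": 0.25}
    )
    softmax_temperature: float = 0.0
    p_skip: float = 0.0
    memory_capacity: int | None = None  # None = unlimited
    p_lapse: float = 0.0
    speed_mean: float = 15.0   # cm/s
    speed_sd: float = 0.0

    def __post_init__(self) -> None:
        w = self.strategy_weights
        unknown = set(w) - set(POLICIES)
        if unknown:
            raise ValueError(f"unknown policies {unknown}")
        total = sum(w.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"strategy weights must sum to 1, got {total}")
        if any(v < 0 for v in w.values()):
            raise ValueError("strategy weights must be non-negative")
        if not 0.0 <= self.p_skip <= 1.0:
            raise ValueError("p_skip must be in [0, 1]")
        if not 0.0 <= self.p_lapse <= 1.0:
            raise ValueError("p_lapse must be in [0, 1]")
        if self.softmax_temperature < 0:
            raise ValueError("softmax_temperature must be >= 0")
        if self.memory_capacity is not None and self.memory_capacity < 0:
            raise ValueError("memory_capacity must be >= 0")


@dataclass(frozen=True)
class MicrogliaMixture:
    """Morphotype mixture weights for one (strain, sex, region) cell."""

    p_ramified: float
    p_amoeboid: float
    p_hypertrophic: float

    def __post_init__(self) -> None:
        total = self.p_ramified + self.p_amoeboid + self.p_hypertrophic
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture must sum to 1, got {total}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_ramified, self.p_amoeboid, self.p_hypertrophic)


@dataclass(frozen=True)
class CohortDesign:
    """Factorial cohort layout: per-cell sample size and agent parameters."""

    n_per_cell: dict[tuple[str, str], int]
    params: dict[tuple[str, str], AgentParams]
    configs: tuple[ArenaConfig, ...]
    microglia_mixtures: dict[tuple[str, str, str], MicrogliaMixture] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for cell, n in self.n_per_cell.items():
            if n < 1:
                raise ValueError(f"cell {cell} needs n >= 1")
            if cell not in self.params:
                raise ValueError(f"cell {cell} has no agent parameters")


@dataclass
class SimulatedCohort:
    """Generated cohort: trial logs with tracks plus ground truth."""

    logs: list[TrialLog]
    ground_truth: pd.DataFrame  # one row per rat: cell + parameters + seed

    def events_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rat_id": lg.rat_id, "strain": lg.strain, "sex": lg.sex,
                "config_id": lg.config_id, "t_sec": t, "target_id": tid,
                "event": kind.value,
            }
            for lg in self.logs
            for t, tid, kind in lg.events
        ]
        return pd.DataFrame(rows)

    def tracks_frame(self) -> pd.DataFrame:
        frames = []
        for lg in self.logs:
            if lg.track is None:
                continue
            df = pd.DataFrame(lg.track, columns=["t_sec", "x_cm", "y_cm"])
            df.insert(0, "config_id", lg.config_id)
            df.insert(0, "rat_id", lg.rat_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _policy_ranks(
    policy: str,
    candidates: list[int],
    position: np.ndarray,
    coords: dict[int, np.ndarray],
    route_orders: dict[str, tuple[int, ...]],
) -> list[int]:
    """Candidates sorted by the policy's preference (most preferred first)."""
    if policy in ("OPTIMAL", "HULL"):
        order = route_orders[policy]
        pos_in = {tid: i for i, tid in enumerate(order)}
        return sorted(candidates, key=lambda t: (pos_in[t], t))
    if policy == "NN":
        return sorted(
            candidates,
            key=lambda t: (float(np.linalg.norm(coords[t] - position)), t),
        )
    raise ValueError(policy)  # RANDOM handled by caller


def simulate_trial(
    params: AgentParams,
    config: ArenaConfig,
    opt: OptimalRouteSet,
    seed: int | np.random.Generator,
) -> TrialLog:
    """Simulate one foraging trial; returns a validated TrialLog with track.

    Raises ``RuntimeError`` if the agent fails to clear the arena within
    ``60 * n_targets`` contacts (pathological parameterisations).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ids = list(config.target_ids)
    coords = {tid: xy for tid, xy in zip(ids, config.coordinates())}
    n = len(ids)

    # trial-fixed route templates for the OPTIMAL and HULL policies
    radius = config.arena_diameter / 2.0
    theta = rng.uniform(0.0, 2.0 * math.pi)
    start_pos = np.array([radius * math.cos(theta), radius * math.sin(theta)])

    opt_order = opt.routes[0].order
    d_first = np.linalg.norm(coords[opt_order[0]] - start_pos)
    d_last = np.linalg.norm(coords[opt_order[-1]] - start_pos)
    if d_last < d_first:
        opt_order = opt_order[::-1]
    nearest_tid = min(ids, key=lambda t: (np.linalg.norm(coords[t] - start_pos), t))
    hull_order = (
        hull_perimeter_route(config, nearest_tid).order if n >= 3 else tuple(ids)
    )
    route_orders = {"OPTIMAL": opt_order, "HULL": hull_order}

    speed = -1.0
    while speed <= 0.1:
        speed = rng.normal(params.speed_mean, params.speed_sd)

    weights = np.array([params.strategy_weights.get(p, 0.0) for p in POLICIES])
    baited = set(ids)
    depleted: list[int] = []  # depletion order, most recent last
    events: list[tuple[float, int, EventKind]] = []
    track: list[tuple[float, float, float]] = [(0.0, *start_pos)]
    position = start_pos
    t = 0.0
    steps = 0
    cap = STEP_CAP_PER_TARGET * n

    while baited:
        steps += 1
        if steps > cap:
            raise RuntimeError(
                f"agent exceeded {cap} contacts on config {config.config_id}; "
                f"check parameters"
            )
        if params.memory_capacity is None:
            forgotten: list[int] = []
        else:
            forgotten = depleted[: max(len(depleted) - params.memory_capacity, 0)]
        candidates = sorted(baited) + [t_ for t_ in forgotten]
        # never immediately re-contact the target we are sitting on
        here = [t_ for t_ in candidates
                if float(np.linalg.norm(coords[t_] - position)) > 1e-9]
        if here:
            candidates = here

        # memory lapse: a depleted target is momentarily believed baited
        # and visited, independent of the route policy
        lapse_pool = [
            t_ for t_ in depleted
            if float(np.linalg.norm(coords[t_] - position)) > 1e-9
        ]
        if lapse_pool and rng.random() < params.p_lapse:
            nxt = lapse_pool[rng.integers(len(lapse_pool))]
            policy = None
        else:
            policy = POLICIES[rng.choice(len(POLICIES), p=weights)]
        if policy is None:
            pass
        elif policy == "RANDOM":
            nxt = candidates[rng.integers(len(candidates))]
        else:
            ranked = _policy_ranks(policy, candidates, position, coords,
                                   route_orders)
            if params.softmax_temperature == 0.0:
                nxt = ranked[0]
            else:
                ranks = np.arange(len(ranked), dtype=float)
                logits = -ranks / params.softmax_temperature
                p = np.exp(logits - logits.max())
                p /= p.sum()
                nxt = ranked[rng.choice(len(ranked), p=p)]

        dist = float(np.linalg.norm(coords[nxt] - position))
        if dist < 1e-9:
            # forced re-contact of the current target (e.g. the last bait
            # was just skipped): brief pause, no displacement
            dt = 0.5
            t += dt
            track.append((t, float(position[0]), float(position[1])))
        else:
            dt = dist / speed
            # straight-segment track samples
            n_samples = max(int(dt * TRACK_HZ), 1)
            for s in range(1, n_samples + 1):
                frac = s / n_samples
                pt = position + frac * (coords[nxt] - position)
                track.append((t + frac * dt, float(pt[0]), float(pt[1])))
            t += dt
            position = coords[nxt]

        events.append((t, nxt, EventKind.CONTACT))
        if nxt in baited:
            if rng.random() < params.p_skip:
                pass  # skip: leave the bait for a later pass
            else:
                events.append((t, nxt, EventKind.RETRIEVAL))
                baited.remove(nxt)
                depleted.append(nxt)
        else:
            # revisit of a forgotten target: it is re-remembered
            depleted.remove(nxt)
            depleted.append(nxt)

    return TrialLog(
        rat_id="sim",
        strain="SHR",
        sex="F",
        config_id=config.config_id,
        events=tuple(events),
        track=np.array(track),
    )


def simulate_cohort(
    design: CohortDesign, seed: int
) -> SimulatedCohort:
    """Simulate every rat of a factorial cohort on every configuration.

    Each rat runs all configurations once, in a rat-specific pseudorandom
    order; per-rat seeds derive from the cohort seed, so cohorts are fully
    reproducible and individual rats re-simulatable.
    """
    master = np.random.default_rng(seed)
    opt_cache = {
        cfg.config_id: optimal_route(distance_matrix(cfg)) for cfg in design.configs
    }
    logs: list[TrialLog] = []
    truth_rows = []
    rat_counter = 0
    for (strain, sex) in sorted(design.n_per_cell):
        n_rats = design.n_per_cell[(strain, sex)]
        params = design.params[(strain, sex)]
        for _ in range(n_rats):
            rat_counter += 1
            rat_id = f"{strain}_{sex}_{rat_counter:02d}"
            rat_seed = int(master.integers(2**31 - 1))
            rat_rng = np.random.default_rng(rat_seed)
            order = rat_rng.permutation(len(design.configs))
            for idx in order:
                cfg = design.configs[idx]
                lg = simulate_trial(params, cfg, opt_cache[cfg.config_id], rat_rng)
                logs.append(
                    TrialLog(
                        rat_id=rat_id, strain=strain, sex=sex,
                        config_id=lg.config_id, events=lg.events, track=lg.track,
                    )
                )
            truth_rows.append(
                {
                    "rat_id": rat_id, "strain": strain, "sex": sex,
                    "seed": rat_seed,
                    "w_optimal": params.strategy_weights.get("OPTIMAL", 0.0),
                    "w_nn": params.strategy_weights.get("NN", 0.0),
                    "w_hull": params.strategy_weights.get("HULL", 0.0),
                    "w_random": params.strategy_weights.get("RANDOM", 0.0),
                    "temperature": params.softmax_temperature,
                    "p_skip": params.p_skip,
                    "p_lapse": params.p_lapse,
                    "memory_capacity": params.memory_capacity,
                    "speed_mean": params.speed_mean,
                    "speed_sd": params.speed_sd,
                }
            )
    return SimulatedCohort(logs=logs, ground_truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# microglia shape generation


def _wavy_disc(
    shape: tuple[int, int],
    centre: tuple[float, float],
    r0: float,
    eps: float,
    k_mode: int,
    phase: float,
    noise: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Disc with sinusoidal boundary modulation plus random rough modes."""
    yy, xx = np.indices(shape)
    dy = yy - centre[0]
    dx = xx - centre[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = r0 * (1.0 + eps * np.sin(k_mode * theta + phase))
    if noise > 0:
        for m in (5, 7, 9):
            amp = noise * rng.uniform(0.0, 0.08)
            ph = rng.uniform(0.0, 2 * math.pi)
            boundary = boundary + r0 * amp * np.sin(m * theta + ph)
    return r <= boundary


def _add_ray(
    mask: np.ndarray,
    centre: tuple[float, float],
    angle: float,
    length: float,
    width: float,
) -> None:
    """Rasterise a thick radial process onto the mask, in place."""
    yy, xx = np.indices(mask.shape)
    dy = yy - centre[0]
    dx = xx - centre[1]
    u = np.array([math.sin(angle), math.cos(angle)])  # (dy, dx) direction
    proj = dy * u[0] + dx * u[1]
    perp = np.abs(dy * u[1] - dx * u[0])
    mask |= (proj >= 0) & (proj <= length) & (perp <= width / 2.0)


def make_cell_mask(
    morph: MorphClass,
    rng: np.random.Generator,
    noise: float = 0.0,
    shape: tuple[int, int] = (128, 128),
) -> np.ndarray:
    """Generate one labelled binary cell mask of the requested morphotype.

    Noiseless shapes respect the classification thresholds with margin:
    ramified somata are nearly circular (circularity ~1.01), amoeboid and
    hypertrophic somata carry strong boundary modulation (circularity well
    above 1.03) with <3 and >=3 thick processes respectively.  ``noise``
    (0..1) scales extra random boundary modes.
    """
    centre = (shape[0] / 2.0, shape[1] / 2.0)
    phase = rng.uniform(0.0, 2 * math.pi)
    if morph is MorphClass.RAMIFIED:
        r0 = rng.uniform(28.0, 34.0)
        mask = _wavy_disc(shape, centre, r0, eps=0.008, k_mode=6,
                          phase=phase, noise=noise, rng=rng)
        return mask
    if morph is MorphClass.AMOEBOID:
        r0 = rng.uniform(24.0, 30.0)
        mask = _wavy_disc(shape, centre, r0, eps=0.09, k_mode=6,
                          phase=phase, noise=noise, rng=rng)
        n_rays = int(rng.integers(0, 3))  # 0-2 processes
        ray_len = r0 * 1.7
    else:
        r0 = rng.uniform(28.0, 34.0)
        mask = _wavy_disc(shape, centre, r0, eps=0.07, k_mode=6,
                          phase=phase, noise=noise, rng=rng)
        n_rays = int(rng.integers(4, 7))  # 4-6 processes
        ray_len = r0 * 1.8
    if n_rays:
        base = rng.uniform(0.0, 2 * math.pi)
        jitter = rng.uniform(-0.25, 0.25, size=n_rays)
        for j in range(n_rays):
            angle = base + 2 * math.pi * j / n_rays + jitter[j]
            _add_ray(mask, centre, angle, length=ray_len, width=5.0)
    return mask


def simulate_microglia(
    mixtures: dict[tuple[str, str, str], MicrogliaMixture],
    rats_per_cell: dict[tuple[str, str], list[str]],
    n_cells: int,
    noise: float,
    seed: int,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Generate labelled cell masks for every (strain, sex, region) cell.

    ``n_cells`` masks are drawn per (rat, region), the morphotype sampled
    from the cell's mixture.  Returns the mask list plus a metadata table
    with one row per mask (``cell_id, rat_id, strain, sex, region,
    true_class``) aligned by position.
    """
    rng = np.random.default_rng(seed)
    classes = list(MorphClass)
    masks: list[np.ndarray] = []
    rows = []
    counter = 0
    for (strain, sex, region), mix in sorted(mixtures.items()):
        for rat_id in rats_per_cell[(strain, sex)]:
            draws = rng.choice(3, size=n_cells, p=mix.as_tuple())
            for d in draws:
                counter += 1
                morph = classes[int(d)]
                masks.append(make_cell_mask(morph, rng, noise=noise))
                rows.append(
                    {
                        "cell_id": f"cell_{counter:05d}",
                        "rat_id": rat_id,
                        "strain": strain,
                        "sex": sex,
                        "region": region,
                        "true_class": morph.value,
                    }
                )
    return masks, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default study-style design


def _weights(optimal: float) -> dict[str, float]:
    """Strategy mixture with the given optimal-route adherence; the
    remainder is split over the local heuristics and random exploration."""
    rest = 1.0 - optimal
    return {
        "OPTIMAL": optimal,
        "NN": rest * 0.30,
        "HULL": rest * 0.20,
        "RANDOM": rest * 0.50,
    }


#: Strain gap in optimal-route adherence used by the default design.  The
#: gap was calibrated by pilot simulation of the mapping from the OPTIMAL
#: weight to per-rat mean proportion of optimal transitions (slope ~0.44
#: per unit weight, between-rat SD ~0.09 at temperature 0.3), targeting
#: ~0.8 analytic power for the strain main effect at nine rats per cell;
#: the resulting group means sit in a realistic range.
DEFAULT_OPTIMAL_WEIGHT_WKY = 0.59
DEFAULT_OPTIMAL_WEIGHT_SHR = 0.41


def default_design(
    configs: Sequence[ArenaConfig],
    n_per_cell: int = 9,
    strain_gap: float | None = None,
    null: bool = False,
) -> CohortDesign:
    """Reference cohort: SHR deficit in route adherence and higher speed,
    male excess in skips, identical memory in every cell.

    With ``null=True`` all four cells share the WKY female parameters, so
    every factorial term is truly null (used for calibration runs).
    """
    w_wky = DEFAULT_OPTIMAL_WEIGHT_WKY
    w_shr = (
        DEFAULT_OPTIMAL_WEIGHT_SHR if strain_gap is None else w_wky - strain_gap
    )
    common = dict(softmax_temperature=0.3, memory_capacity=None, p_lapse=0.06)
    p_skip = {"F": 0.01, "M": 0.035}
    speed = {"SHR": 20.4, "WKY": 12.4}  # cm/s, realistic strain means
    cells = {}
    for strain in ("SHR", "WKY"):
        for sex in ("F", "M"):
            if null:
                cells[(strain, sex)] = AgentParams(
                    strategy_weights=_weights(w_wky),
                    p_skip=p_skip["F"],
                    speed_mean=speed["WKY"], speed_sd=2.0,
                    **common,
                )
            else:
                cells[(strain, sex)] = AgentParams(
                    strategy_weights=_weights(
                        w_shr if strain == "SHR" else w_wky
                    ),
                    p_skip=p_skip[sex],
                    speed_mean=speed[strain], speed_sd=2.0,
                    **common,
                )
    mixtures = {}
    base = MicrogliaMixture(0.55, 0.15, 0.30)
    elevated = MicrogliaMixture(0.40, 0.15, 0.45)
    for strain in ("SHR", "WKY"):
        for sex in ("F", "M"):
            for region in ("PrL", "IL", "CA1", "CA3", "DG", "MEC"):
                if not null and strain == "SHR" and region in ("IL", "DG"):
                    mixtures[(strain, sex, region)] = elevated
                else:
                    mixtures[(strain, sex, region)] = base
    return CohortDesign(
        n_per_cell={c: n_per_cell for c in cells},
        params=cells,
        configs=tuple(configs),
        microglia_mixtures=mixtures,
    )
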