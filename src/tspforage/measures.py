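"""Trial-log parsing and behavioural scoring.

A trial is one rat foraging one configuration.  Experimenters code an
ordered sequence of target *contacts* (whisker/nose/forepaw touch) and bait
*retrievals*; from that sequence the module derives the task's nine
behavioural statistics.  Transitions are the straight line segments between successive
(distinct) target contacts; travel distance is the sum of those segment
lengths, deliberately ignoring the meandering of the actual path — the
tracked path enters only through velocity.

Scoring definitions
-------------------
revisit
    contact with a target whose bait was retrieved at a strictly earlier
    event (a spatial-memory error).
skip
    contact with a still-baited target with no retrieval at that moment
    (an attention/motivation lapse); a later successful retrieval does not
    erase the skip.
span
    number of distinct targets contacted *and* retrieved before the first
    revisit (memory span; equals the target count on a revisit-free trial).
PAO
    travel distance in excess of the optimal route length, reported both as
    a difference in cm and as a percentage of the optimal length.
PropOpt / prop_dist_opt
    fraction of transitions (respectively, of travel distance) whose
    undirected edge belongs to some optimal route.
rate
    mean transition length: travel distance / number of transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import ArenaConfig, distance_matrix
from .routes import OptimalRouteSet

__all__ = [
    "EventKind",
    "TrialLog",
    "TrialMeasures",
    "TransitionMap",
    "parse_event_log",
    "write_event_log",
    "read_track_table",
    "compute_measures",
    "velocity_from_track",
    "transition_maps",
    "measures_table",
]


class EventKind(str, Enum):
    CONTACT = "contact"
    RETRIEVAL = "retrieval"


class EventLogError(ValueError):
    """Malformed or invariant-violating trial events."""


@dataclass(frozen=True)
class TrialLog:
    """Coded events of one rat on one configuration.

    ``events`` are time-ordered ``(t_sec, target_id, kind)`` triples; a
    retrieval of a target must be preceded (at the same or an earlier time)
    by a contact of that target, and each target is retrieved at most once.
    ``track`` optionally holds ``(t, x, y)`` position samples for velocity.
    """

    rat_id: str
    strain: str
    sex: str
    config_id: int
    events: tuple[tuple[float, int, EventKind], ...]
    track: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.events:
            raise EventLogError(f"rat {self.rat_id}: empty trial")
        times = [e[0] for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise EventLogError(f"rat {self.rat_id}: events out of time order")
        contacted: set[int] = set()
        retrieved: set[int] = set()
        for i, (t, tid, kind) in enumerate(self.events):
            if kind is EventKind.CONTACT:
                contacted.add(tid)
            else:
                if tid not in contacted:
                    raise EventLogError(
                        f"rat {self.rat_id}: retrieval of target {tid} at "
                        f"event {i} without a prior contact"
                    )
                if tid in retrieved:
                    raise EventLogError(
                        f"rat {self.rat_id}: duplicate retrieval of target {tid}"
                    )
                retrieved.add(tid)

    @property
    def contact_sequence(self) -> tuple[int, ...]:
        return tuple(tid for _, tid, k in self.events if k is EventKind.CONTACT)


@dataclass(frozen=True)
class TrialMeasures:
    """The behavioural statistics of one trial.

    Transition-dependent fields (``travel_distance`` onward) are ``nan``
    when the trial has fewer than two distinct successive contacts — they
    are undefined, not zero.
    """

    rat_id: str
    strain: str
    sex: str
    config_id: int
    latency: float
    n_contacts: int
    revisits: int
    revisits_per_target: float
    skips: int
    span: int
    n_transitions: int
    travel_distance: float
    pao_diff: float
    pao_pct: float
    rate: float
    prop_opt: float
    prop_dist_opt: float
    velocity: float = math.nan


@dataclass(frozen=True)
class TransitionMap:
    """Pooled inter-target transition probabilities for one group."""

    strain: str
    sex: str
    config_id: int
    target_ids: tuple[int, ...]
    p: np.ndarray = field(repr=False)
    n_transitions: int = 0


# ---------------------------------------------------------------------------
# file IO


_EVENT_COLUMNS = ["rat_id", "strain", "sex", "config_id", "t_sec", "target_id",
                  "event"]


def parse_event_log(path: str | Path) -> list[TrialLog]:
    """Read a delimited event-log table into validated trial logs.

    Columns: ``rat_id, strain, sex, config_id, t_sec, target_id, event``
    with ``event`` in ``{contact, retrieval}``.  One :class:`TrialLog` is
    produced per ``(rat_id, config_id)`` pair.  Invariant violations are
    reported with the offending row.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise EventLogError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[~df["event"].isin([k.value for k in EventKind])]
    if len(bad):
        raise EventLogError(
            f"{path}: unknown event {df.loc[bad[0], 'event']!r} at line "
            f"{bad[0] + 2}"
        )
    logs: list[TrialLog] = []
    for (rat, cid), sub in df.groupby(["rat_id", "config_id"], sort=True):
        sub = sub.sort_values("t_sec", kind="stable")
        strains = sub["strain"].unique()
        sexes = sub["sex"].unique()
        if len(strains) > 1 or len(sexes) > 1:
            raise EventLogError(
                f"{path}: inconsistent strain/sex metadata for rat {rat}"
            )
        events = tuple(
            (float(r.t_sec), int(r.target_id), EventKind(r.event))
            for r in sub.itertuples()
        )
        try:
            logs.append(
                TrialLog(
                    rat_id=str(rat),
                    strain=str(strains[0]),
                    sex=str(sexes[0]),
                    config_id=int(cid),
                    events=events,
                )
            )
        except EventLogError as exc:
            first_row = int(sub.index[0]) + 2
            raise EventLogError(f"{path} (rows from line {first_row}): {exc}")
    return logs


def write_event_log(logs: Iterable[TrialLog], path: str | Path) -> None:
    """Write trial logs as the delimited table ``parse_event_log`` reads."""
    rows = [
        {
            "rat_id": lg.rat_id,
            "strain": lg.strain,
            "sex": lg.sex,
            "config_id": lg.config_id,
            "t_sec": t,
            "target_id": tid,
            "event": kind.value,
        }
        for lg in logs
        for t, tid, kind in lg.events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Read a position-track table (``rat_id, config_id, t_sec, x_cm, y_cm``).

    Tolerates a leading header block of non-tabular lines (video-tracking
    exports often prepend metadata): lines before the column header are
    skipped.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path) as fh:
        lines = fh.readlines()
    header_row = None
    for i, line in enumerate(lines):
        cols = [c.strip().lower() for c in line.strip().split(sep)]
        if {"t_sec", "x_cm", "y_cm"} <= set(cols):
            header_row = i
            break
    if header_row is None:
        raise EventLogError(f"{path}: no track header (t_sec, x_cm, y_cm) found")
    df = pd.read_csv(path, sep=sep, skiprows=header_row)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def attach_tracks(logs: Sequence[TrialLog], tracks: pd.DataFrame) -> list[TrialLog]:
    """Return copies of ``logs`` with matching position tracks attached."""
    out = []
    for lg in logs:
        sub = tracks[
            (tracks["rat_id"].astype(str) == lg.rat_id)
            & (tracks["config_id"].astype(int) == lg.config_id)
        ]
        track = None
        if len(sub) >= 2:
            track = sub[["t_sec", "x_cm", "y_cm"]].to_numpy(float)
        out.append(
            TrialLog(
                rat_id=lg.rat_id,
                strain=lg.strain,
                sex=lg.sex,
                config_id=lg.config_id,
                events=lg.events,
                track=track,
            )
        )
    return out


# ---------------------------------------------------------------------------
# scoring


def _collapsed_contacts(log: TrialLog) -> list[tuple[float, int]]:
    """Contact (t, target) sequence with consecutive repeats collapsed.

    Zero-length transitions would corrupt rate and the distance-weighted
    optimality fraction, so immediately repeated contacts of one target
    count as a single visit bout.
    """
    seq: list[tuple[float, int]] = []
    for t, tid, kind in log.events:
        if kind is EventKind.CONTACT and (not seq or seq[-1][1] != tid):
            seq.append((t, tid))
    return seq


def velocity_from_track(track: np.ndarray) -> float:
    """Mean travel velocity (cm/s) from a ``(t, x, y)`` sample array."""
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[0] < 2 or track.shape[1] != 3:
        raise ValueError("track needs >=2 (t, x, y) samples")
    t = track[:, 0]
    if np.any(np.diff(t) <= 0):
        raise ValueError("track times must be strictly increasing")
    duration = t[-1] - t[0]
    steps = np.linalg.norm(np.diff(track[:, 1:], axis=0), axis=1)
    return float(steps.sum() / duration)


def compute_measures(
    log: TrialLog,
    config: ArenaConfig,
    opt: OptimalRouteSet,
) -> TrialMeasures:
    """Score one trial against its configuration's optimal route set."""
    if log.config_id != config.config_id:
        raise ValueError(
            f"log is for config {log.config_id}, geometry for "
            f"{config.config_id}"
        )
    dm = distance_matrix(config)
    n_targets = config.n_targets

    retrieval_time: dict[int, float] = {}
    retrieval_event_idx: dict[int, int] = {}
    for i, (t, tid, kind) in enumerate(log.events):
        if kind is EventKind.RETRIEVAL:
            retrieval_time[tid] = t
            retrieval_event_idx[tid] = i

    # collapsed contact bouts with their first raw event position; a
    # retrieval between two contacts of the same target does not split the
    # bout
    contacts: list[tuple[int, float, int]] = []  # (raw_pos, t, target)
    last_tid: int | None = None
    for i, (t, tid, kind) in enumerate(log.events):
        if kind is not EventKind.CONTACT:
            continue
        if tid != last_tid:
            contacts.append((i, t, tid))
        last_tid = tid
    n_contacts = sum(1 for *_, k in log.events if k is EventKind.CONTACT)

    revisits = 0
    skips = 0
    first_revisit_pos: int | None = None
    for pos, t, tid in contacts:
        already_retrieved = (
            tid in retrieval_event_idx and retrieval_event_idx[tid] < pos
        )
        if already_retrieved:
            revisits += 1
            if first_revisit_pos is None:
                first_revisit_pos = pos
        elif retrieval_time.get(tid) != t:
            # still baited, no retrieval at this moment
            skips += 1

    # span: distinct targets contacted-and-retrieved before the first
    # revisit (all retrieved targets on a revisit-free trial)
    if first_revisit_pos is None:
        span = len(retrieval_event_idx)
    else:
        span = sum(
            1 for i in retrieval_event_idx.values() if i < first_revisit_pos
        )

    # transitions over the collapsed contact sequence
    seq = [tid for *_, tid in contacts]
    n_transitions = max(len(seq) - 1, 0)
    if n_transitions >= 1:
        dists = np.array(
            [dm.between(a, b) for a, b in zip(seq, seq[1:])], dtype=float
        )
        on_opt = np.array(
            [opt.contains_edge(a, b) for a, b in zip(seq, seq[1:])], dtype=bool
        )
        travel_distance = float(dists.sum())
        rate = travel_distance / n_transitions
        prop_opt = float(on_opt.sum() / n_transitions)
        prop_dist_opt = float(dists[on_opt].sum() / travel_distance)
        pao_diff = travel_distance - opt.optimal_length
        pao_pct = 100.0 * pao_diff / opt.optimal_length
    else:
        travel_distance = rate = prop_opt = prop_dist_opt = math.nan
        pao_diff = pao_pct = math.nan

    if retrieval_time:
        latency = max(retrieval_time.values()) - log.events[0][0]
    else:
        latency = log.events[-1][0] - log.events[0][0]

    velocity = math.nan
    if log.track is not None:
        velocity = velocity_from_track(log.track)

    return TrialMeasures(
        rat_id=log.rat_id,
        strain=log.strain,
        sex=log.sex,
        config_id=log.config_id,
        latency=float(latency),
        n_contacts=n_contacts,
        revisits=revisits,
        revisits_per_target=revisits / n_targets,
        skips=skips,
        span=span,
        n_transitions=n_transitions,
        travel_distance=travel_distance,
        pao_diff=pao_diff,
        pao_pct=pao_pct,
        rate=rate,
        prop_opt=prop_opt,
        prop_dist_opt=prop_dist_opt,
        velocity=velocity,
    )


def measures_table(measures: Iterable[TrialMeasures]) -> pd.DataFrame:
    """One row per (rat, configuration) with every statistic as a column."""
    return pd.DataFrame([vars(m) for m in measures])


def transition_maps(
    logs: Sequence[TrialLog],
    configs: dict[int, ArenaConfig],
) -> list[TransitionMap]:
    """Group-level transition probability maps, one per
    (strain, sex, config)."""
    keyed: dict[tuple[str, str, int], list[TrialLog]] = {}
    for lg in logs:
        keyed.setdefault((lg.strain, lg.sex, lg.config_id), []).append(lg)
    maps: list[TransitionMap] = []
    for (strain, sex, cid), group in sorted(keyed.items()):
        config = configs[cid]
        ids = config.target_ids
        index = {tid: i for i, tid in enumerate(ids)}
        counts = np.zeros((len(ids), len(ids)))
        for lg in group:
            seq = [tid for _, tid in _collapsed_contacts(lg)]
            for a, b in zip(seq, seq[1:]):
                counts[index[a], index[b]] += 1
        total = counts.sum()
        if total == 0:
            continue  # no transitions observed in this group
        maps.append(
            TransitionMap(
                strain=strain,
                sex=sex,
                config_id=cid,
                target_ids=ids,
                p=counts / total,
                n_transitions=int(total),
            )
        )
    return maps
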