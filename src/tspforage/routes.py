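"""Exact and heuristic route models for target configurations.

The headline quantity is the *optimal route*: the shortest open Hamiltonian
path over the targets (rats are not required to return to their start, so
OPEN with free endpoints is the default; CLOSED tours and anchored searches
are available for sensitivity analyses).  The exact solver is a Held–Karp
dynamic programme over target subsets, feasible well past the ten-target
maximum used in the arena.  Because symmetric layouts admit ties, the solver
enumerates *every* optimal route within a tolerance and exposes the union of
their undirected edges; behavioural scoring credits a transition if its edge
lies in that union.

Two strategy models mirror the heuristics rats are hypothesised to use:
greedy nearest-neighbour (L-NN) and the hull/perimeter walk (L-P).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .geometry import ArenaConfig, DistanceMatrix, distance_matrix

__all__ = [
    "RouteMode",
    "RouteSolution",
    "OptimalRouteSet",
    "optimal_route",
    "brute_force_routes",
    "nearest_neighbor_route",
    "hull_perimeter_route",
]

#: Exact-solver ceiling; the behavioural task never exceeds ten targets.
MAX_EXACT_N = 20
#: Exhaustive-enumeration ceiling for the brute-force oracle.
MAX_BRUTE_N = 9


class RouteMode(str, Enum):
    OPEN = "OPEN"       # Hamiltonian path, no return leg
    CLOSED = "CLOSED"   # Hamiltonian tour


@dataclass(frozen=True)
class RouteSolution:
    """A single route: a visiting order of target ids and its length."""

    order: tuple[int, ...]
    length: float
    mode: RouteMode
    anchor: int | None = None

    def edges(self) -> frozenset[frozenset[int]]:
        pairs = list(zip(self.order, self.order[1:]))
        if self.mode is RouteMode.CLOSED:
            pairs.append((self.order[-1], self.order[0]))
        return frozenset(frozenset(p) for p in pairs)

    def to_dict(self) -> dict:
        return {
            "order": list(self.order),
            "length": self.length,
            "mode": self.mode.value,
            "anchor": self.anchor,
        }


@dataclass(frozen=True)
class OptimalRouteSet:
    """All minimum-length routes for a configuration plus their edge union."""

    optimal_length: float
    routes: tuple[RouteSolution, ...]
    edge_union: frozenset[frozenset[int]]
    mode: RouteMode
    anchor: int | None = None

    def contains_edge(self, tid_a: int, tid_b: int) -> bool:
        return frozenset((tid_a, tid_b)) in self.edge_union


def _route_length(d: np.ndarray, perm: tuple[int, ...], closed: bool) -> float:
    length = float(sum(d[perm[i], perm[i + 1]] for i in range(len(perm) - 1)))
    if closed:
        length += float(d[perm[-1], perm[0]])
    return length


def _canonical(
    perm: tuple[int, ...], closed: bool, anchored: bool = False
) -> tuple[int, ...]:
    """Collapse traversal duplicates: reversal for paths; rotation+reversal
    for tours.  Anchored paths keep their orientation (start is fixed)."""
    if not closed:
        if anchored:
            return perm
        rev = perm[::-1]
        return min(perm, rev)
    n = len(perm)
    best = None
    for seq in (perm, perm[::-1]):
        start = seq.index(min(seq))
        rot = seq[start:] + seq[:start]
        if best is None or rot < best:
            best = rot
    return best


def _build_set(
    dm: DistanceMatrix,
    perms: set[tuple[int, ...]],
    optimal_length: float,
    mode: RouteMode,
    anchor: int | None,
) -> OptimalRouteSet:
    ids = dm.target_ids
    closed = mode is RouteMode.CLOSED
    routes = tuple(
        RouteSolution(
            order=tuple(ids[i] for i in perm),
            length=_route_length(dm.d, perm, closed),
            mode=mode,
            anchor=anchor,
        )
        for perm in sorted(perms)
    )
    union: set[frozenset[int]] = set()
    for r in routes:
        union |= r.edges()
    return OptimalRouteSet(
        optimal_length=optimal_length,
        routes=routes,
        edge_union=frozenset(union),
        mode=mode,
        anchor=anchor,
    )


def optimal_route(
    dm: DistanceMatrix,
    mode: RouteMode = RouteMode.OPEN,
    anchor: int | None = None,
    tol: float | None = None,
) -> OptimalRouteSet:
    """Exact optimal route(s) by Held–Karp dynamic programming.

    Parameters
    ----------
    dm
        Distance matrix of the configuration.
    mode
        ``OPEN`` (default): shortest Hamiltonian path, endpoints free unless
        ``anchor`` fixes one end.  ``CLOSED``: shortest tour.
    anchor
        Optional target id fixed as one path endpoint (OPEN mode).
    tol
        Absolute length tolerance for tie enumeration; defaults to
        ``1e-9 * optimal_length``.  All routes within ``tol`` of the optimum
        are returned and contribute to the edge union.

    Raises
    ------
    ValueError
        If ``n > 20`` (exact solver only) or ``n < 2``.
    """
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 targets")
    if n > MAX_EXACT_N:
        raise ValueError(f"exact solver limited to n <= {MAX_EXACT_N}, got {n}")
    if tol is not None and tol < 0:
        raise ValueError("tol must be >= 0")
    d = dm.d
    closed = mode is RouteMode.CLOSED

    anchor_idx: int | None = None
    if anchor is not None:
        anchor_idx = dm.target_ids.index(anchor)

    # g[S][j]: shortest path visiting exactly the targets in bitmask S and
    # ending at j.  Paths start at the anchor when given (or at vertex 0 for
    # tours, exploiting rotation invariance), otherwise anywhere.
    full = (1 << n) - 1
    INF = np.inf
    g = np.full((1 << n, n), INF)
    if closed:
        g[1 << 0, 0] = 0.0
    elif anchor_idx is not None:
        g[1 << anchor_idx, anchor_idx] = 0.0
    else:
        for j in range(n):
            g[1 << j, j] = 0.0

    for S in range(1, full + 1):
        row = g[S]
        if not np.isfinite(row).any():
            continue
        members = [j for j in range(n) if S >> j & 1]
        for j in members:
            cj = row[j]
            if not np.isfinite(cj):
                continue
            for k in range(n):
                if S >> k & 1:
                    continue
                S2 = S | (1 << k)
                cand = cj + d[j, k]
                if cand < g[S2, k]:
                    g[S2, k] = cand

    if closed:
        finals = g[full] + d[:, 0]
        optimal_length = float(finals.min())
    else:
        optimal_length = float(g[full].min())
    if tol is None:
        tol = 1e-9 * max(optimal_length, 1.0)

    budget = optimal_length + tol
    # Backtrack every path whose total length is within budget; g is an
    # exact completion bound, so the search is complete and tightly pruned.
    perms: set[tuple[int, ...]] = set()

    def backtrack(S: int, j: int, tail_cost: float, suffix: list[int]) -> None:
        if g[S, j] + tail_cost > budget + 1e-12:
            return
        if S.bit_count() == 1:
            perms.add(
                _canonical(tuple([j] + suffix), closed, anchor_idx is not None)
            )
            return
        Sprev = S & ~(1 << j)
        for i in range(n):
            if Sprev >> i & 1:
                backtrack(Sprev, i, tail_cost + d[i, j], [j] + suffix)

    if closed:
        for j in range(1, n):
            backtrack(full, j, float(d[j, 0]), [])
        if n == 1:  # pragma: no cover - excluded by n >= 2
            perms.add((0,))
    else:
        for j in range(n):
            backtrack(full, j, 0.0, [])

    return _build_set(dm, perms, optimal_length, mode, anchor)


def brute_force_routes(
    dm: DistanceMatrix,
    mode: RouteMode = RouteMode.OPEN,
    anchor: int | None = None,
    tol: float | None = None,
) -> OptimalRouteSet:
    """Exhaustive-permutation oracle; same contract as :func:`optimal_route`.

    Refuses ``n > 9`` — factorial enumeration only.
    """
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 targets")
    if n > MAX_BRUTE_N:
        raise ValueError(f"brute force limited to n <= {MAX_BRUTE_N}, got {n}")
    d = dm.d
    closed = mode is RouteMode.CLOSED
    anchor_idx = None if anchor is None else dm.target_ids.index(anchor)

    best = np.inf
    scored: list[tuple[float, tuple[int, ...]]] = []
    for perm in itertools.permutations(range(n)):
        if anchor_idx is not None and not closed and perm[0] != anchor_idx:
            continue
        length = _route_length(d, perm, closed)
        scored.append((length, perm))
        best = min(best, length)
    if tol is None:
        tol = 1e-9 * max(best, 1.0)
    perms = {
        _canonical(perm, closed, anchor_idx is not None and not closed)
        for length, perm in scored
        if length <= best + tol + 1e-12
    }
    return _build_set(dm, perms, float(best), mode, anchor)


def nearest_neighbor_route(dm: DistanceMatrix, start: int) -> RouteSolution:
    """Greedy L-NN model: repeatedly move to the nearest unvisited target.

    Distance ties are broken toward the lowest target id, so the route is
    deterministic.
    """
    ids = dm.target_ids
    cur = ids.index(start)  # raises ValueError on unknown id
    order = [cur]
    remaining = set(range(dm.n)) - {cur}
    length = 0.0
    while remaining:
        # lexicographic (distance, target_id) minimum
        nxt = min(remaining, key=lambda j: (dm.d[cur, j], ids[j]))
        length += float(dm.d[cur, nxt])
        order.append(nxt)
        remaining.remove(nxt)
        cur = nxt
    return RouteSolution(
        order=tuple(ids[i] for i in order),
        length=length,
        mode=RouteMode.OPEN,
        anchor=start,
    )


def hull_perimeter_route(config: ArenaConfig, start: int) -> RouteSolution:
    """L-P ("hull") model: walk the convex hull of the targets, then sweep
    the interior by nearest-neighbour.

    The walk begins at the hull vertex nearest ``start`` (``start`` itself
    when it lies on the hull) and proceeds around the hull in whichever
    direction gives the shorter hull walk; interior targets are then
    appended greedily from the last hull target.  Collinear layouts fall
    back to a sweep along the line from the end nearest ``start``.
    """
    if config.n_targets < 3:
        raise ValueError("hull route needs at least 3 targets")
    dm = distance_matrix(config)
    ids = config.target_ids
    xy = config.coordinates()
    start_idx = config.index_of(start)

    try:
        hull = ConvexHull(xy)
        hull_idx = list(hull.vertices)  # counter-clockwise order
    except QhullError:
        # collinear: sweep along the line from the end nearest start
        axis = xy - xy.mean(axis=0)
        direction = np.linalg.svd(axis, full_matrices=False)[2][0]
        proj = axis @ direction
        sweep = list(np.argsort(proj, kind="stable"))
        if dm.d[start_idx, sweep[-1]] < dm.d[start_idx, sweep[0]]:
            sweep = sweep[::-1]
        order = sweep
        length = float(sum(dm.d[a, b] for a, b in zip(order, order[1:])))
        return RouteSolution(
            order=tuple(ids[i] for i in order),
            length=length,
            mode=RouteMode.OPEN,
            anchor=start,
        )

    # rotate the hull cycle to begin at the vertex nearest the start target
    k0 = min(range(len(hull_idx)), key=lambda k: (dm.d[start_idx, hull_idx[k]],
                                                  ids[hull_idx[k]]))
    cyc = hull_idx[k0:] + hull_idx[:k0]
    forward = cyc
    backward = [cyc[0]] + cyc[1:][::-1]

    def walk_len(seq: list[int]) -> float:
        return float(sum(dm.d[a, b] for a, b in zip(seq, seq[1:])))

    hull_walk = min((forward, backward), key=walk_len)

    interior = [i for i in range(config.n_targets) if i not in set(hull_idx)]
    order = list(hull_walk)
    cur = order[-1]
    remaining = set(interior)
    while remaining:
        nxt = min(remaining, key=lambda j: (dm.d[cur, j], ids[j]))
        order.append(nxt)
        remaining.remove(nxt)
        cur = nxt
    length = float(sum(dm.d[a, b] for a, b in zip(order, order[1:])))
    return RouteSolution(
        order=tuple(ids[i] for i in order),
        length=length,
        mode=RouteMode.OPEN,
        anchor=start,
    )
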