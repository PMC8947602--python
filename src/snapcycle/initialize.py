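"""Trajectory initialization from joint histograms.

Each image's joint 2-D histogram induces a directed graph: one vertex per
non-zero cell, edges between cells adjacent along one histogram axis.  Edge
costs encode prior knowledge of the cycle: E2F levels may step by one in
either direction (cost 0); EdU patterns advance negative->diffuse->punctate
and pH3 patterns negative->punctate->diffuse (cost 0 forward, infinite
backward).  The initial trajectory is the minimum-cost sequence of edges that
visits every vertex; a vertex may be split (visited more than once, e.g. for
the two E2F4 waves) at a cost of 1 per split, its proportion divided equally
among the copies.  Vertex proportions then translate into runs of circular
time bins, proportionally to the fraction of cells observed in the cell state
(an asynchronous population spends time in a state in proportion to its
duration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import groupby

import numpy as np
import pandas as pd

from .markers import Couple, is_e2f, is_state
from .quantize import JointHistogram, joint_histogram

__all__ = [
    "TransitionGraph",
    "VertexSequence",
    "NoCoveringSequenceError",
    "build_graph",
    "min_cost_sequence",
    "sequence_to_trajectory",
    "initialize_all",
]

#: finite stand-in cost for a forbidden transition when the strict search is
#: relaxed on degenerate histograms (see initialize_all)
FORBIDDEN_COST = 1.0e6


class NoCoveringSequenceError(RuntimeError):
    """No finite-cost sequence covering all vertices exists within the budget."""


@dataclass
class TransitionGraph:
    pair: tuple[str, str]
    cells: list[tuple[int, int]]  # lexicographically sorted
    proportions: np.ndarray
    costs: dict  # (i, j) -> 0.0 or inf, for histogram-adjacent cell pairs

    @property
    def n_vertices(self) -> int:
        return len(self.cells)

    @property
    def n_edges(self) -> int:
        return len(self.costs)

    def finite_neighbors(self, i: int) -> list[int]:
        return sorted(j for (a, j), c in self.costs.items() if a == i and c == 0.0)

    def all_neighbors(self, i: int) -> list[int]:
        return sorted(j for (a, j) in self.costs if a == i)


def _axis_step_cost(marker: str, u_from: int, u_to: int) -> float:
    """Cost of a one-position step along one histogram axis."""
    if is_e2f(marker):
        return 0.0  # level +/-1 allowed both ways
    # state axes are ordered temporally; only the forward step is free
    return 0.0 if u_to == u_from + 1 else math.inf


def build_graph(hist: JointHistogram) -> TransitionGraph:
    """Transition graph over the non-zero cells of a joint histogram."""
    nz = np.argwhere(hist.counts > 0)
    if nz.size == 0:
        raise ValueError("histogram has no non-zero cell")
    cells = sorted(map(tuple, nz.tolist()))
    index = {c: i for i, c in enumerate(cells)}
    H = hist.H
    proportions = np.array([H[c] for c in cells])
    costs: dict = {}
    m1, m2 = hist.pair
    for c1 in cells:
        for axis, marker in ((0, m1), (1, m2)):
            for delta in (-1, 1):
                c2 = list(c1)
                c2[axis] += delta
                c2 = tuple(c2)
                if c2 in index:
                    costs[(index[c1], index[c2])] = _axis_step_cost(
                        marker, c1[axis], c2[axis]
                    )
    return TransitionGraph(hist.pair, cells, proportions, costs)


@dataclass
class VertexSequence:
    """Ordered cells of a covering sequence; split vertices appear repeatedly."""

    cells: list[tuple[int, int]]
    proportions: list[float]  # per element, after equal division across copies
    cost: float
    n_splits: int
    n_forbidden: int = 0


def _wrap_penalty(graph: TransitionGraph, end: int, start: int) -> int:
    """Implausibility of closing the cycle from the last cell back to the first.

    The reconstructed trajectory is circular, so among equal-cost covering
    sequences the one whose wrap-around transition is itself a small legal
    step describes the cycle best.  Level axes contribute the absolute level
    difference; state axes the forward cyclic distance in temporal order (so
    the legal returns, EdU punctate->negative and pH3 diffuse->negative,
    count 1 while backward steps count 2).
    """
    c_end, c_start = graph.cells[end], graph.cells[start]
    penalty = 0
    for axis, marker in enumerate(graph.pair):
        if is_e2f(marker):
            penalty += abs(c_start[axis] - c_end[axis])
        else:
            penalty += (c_start[axis] - c_end[axis]) % 3
    return penalty


class _SearchBudgetExceeded(Exception):
    pass


def _search(
    graph: TransitionGraph,
    splits: int,
    forbidden: int,
    max_wrap: int | None,
    node_cap: int | None = None,
):
    """Lexicographically-first covering order using exactly the given budgets.

    Depth-first search over vertex orders with memoized failure states; a
    sequence is accepted only if its wrap-around penalty is at most
    ``max_wrap`` (no constraint when None).  Returns a list of vertex indices
    (with repeats for splits) or None; raises ``_SearchBudgetExceeded`` when
    more than ``node_cap`` nodes are expanded.
    """
    n = graph.n_vertices
    if n == 1 and splits == 0 and forbidden == 0:
        return [0]
    nodes = [0]
    finite = {i: graph.finite_neighbors(i) for i in range(n)}
    # relaxed moves: any non-zero-cost transition, i.e. a forbidden adjacent
    # edge or a jump between non-adjacent cells (degenerate histograms can
    # leave the finite-edge graph disconnected)
    relaxed = {
        i: [j for j in range(n) if j != i and j not in finite[i]] for i in range(n)
    }
    failed: set = set()
    target_len = n + splits

    def reachable_ok(visits, last) -> bool:
        """All unvisited vertices reachable from ``last`` via unvisited ones."""
        targets = {v for v in range(n) if visits[v] == 0}
        if not targets:
            return True
        seen = {last}
        stack = [last]
        while stack:
            v = stack.pop()
            for w in finite[v]:
                if w not in seen and (visits[w] == 0 or w == last):
                    seen.add(w)
                    stack.append(w)
        return targets <= seen

    def dfs(order, visits, last, splits_left, forb_left):
        nodes[0] += 1
        if node_cap is not None and nodes[0] > node_cap:
            raise _SearchBudgetExceeded
        if len(order) == target_len:
            if any(v == 0 for v in visits):
                return None
            if max_wrap is not None and _wrap_penalty(graph, last, order[0]) > max_wrap:
                return None
            return list(order)
        if splits_left == 0 and forb_left == 0 and not reachable_ok(visits, last):
            return None
        key = (tuple(visits), last, splits_left, forb_left)
        if key in failed:
            return None
        candidates = [(j, 0) for j in finite[last]]
        if forb_left > 0:
            candidates += [(j, 1) for j in relaxed[last]]
        candidates.sort(key=lambda t: (graph.cells[t[0]], t[1]))
        for j, uses_forbidden in candidates:
            split_cost = 1 if visits[j] >= 1 else 0
            if split_cost and splits_left == 0:
                continue
            if uses_forbidden and forb_left == 0:
                continue
            visits[j] += 1
            order.append(j)
            res = dfs(order, visits, j, splits_left - split_cost,
                      forb_left - uses_forbidden)
            if res is not None:
                return res
            order.pop()
            visits[j] -= 1
        failed.add(key)
        return None

    for start in range(n):  # cells are lex sorted, so starts are tried in order
        failed.clear()  # wrap acceptance depends on the start vertex
        visits = [0] * n
        visits[start] = 1
        res = dfs([start], visits, start, splits, forbidden)
        if res is not None:
            return res
    return None


def min_cost_sequence(
    graph: TransitionGraph, max_splits: int = 3, max_forbidden: int = 0
) -> VertexSequence:
    """Exact minimum-cost covering sequence with at most ``max_splits`` splits.

    Iterative deepening over the number of splits guarantees minimality.
    Among minimum-cost sequences, the one with the most plausible wrap-around
    transition is preferred (the trajectory is circular, so a covering
    sequence is a cut cycle and its endpoints should describe a small legal
    step; see ``_wrap_penalty``); remaining ties are broken by the
    lexicographically smallest cell order, starting vertex first.  With ``max_forbidden > 0`` the search may additionally traverse up
    to that many relaxed transitions -- a forbidden (infinite-cost) edge or a
    jump between non-adjacent cells -- each charged ``FORBIDDEN_COST``.
    Relaxed transitions are minimized before splits; they are needed only on
    degenerate histograms whose finite-edge graph admits no covering sequence
    (e.g. when simultaneous level/state switches leave cells isolated).
    """
    n = graph.n_vertices
    wrap_budgets = sorted(
        {_wrap_penalty(graph, e, s) for e in range(n) for s in range(n) if e != s}
    ) or [0]
    for forb in range(max_forbidden + 1):
        for splits in range(max_splits + 1):
            order = _search(graph, splits, forb, None)
            if order is None:
                continue  # no sequence at this cost at all
            # secondary criterion, best effort under a node budget: the most
            # cycle-consistent wrap-around among minimum-cost sequences
            baseline_wrap = _wrap_penalty(graph, order[-1], order[0])
            for wrap in wrap_budgets:
                if wrap >= baseline_wrap:
                    break
                try:
                    better = _search(graph, splits, forb, wrap, node_cap=300_000)
                except _SearchBudgetExceeded:
                    continue  # this wrap level is too hard; try a looser one
                if better is not None:
                    order = better
                    break
            counts = {i: order.count(i) for i in set(order)}
            cells = [graph.cells[i] for i in order]
            props = [graph.proportions[i] / counts[i] for i in order]
            return VertexSequence(
                cells, props, splits + forb * FORBIDDEN_COST, splits, forb
            )
    raise NoCoveringSequenceError(
        f"no covering sequence within {max_splits} splits"
        + (f" and {max_forbidden} forbidden transitions" if max_forbidden else "")
    )


def sequence_to_trajectory(seq: VertexSequence, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Expand a covering sequence into per-bin values over ``n_bins`` bins.

    Each element occupies a run of consecutive bins whose length is its
    proportion times ``n_bins``, rounded by largest remainder (ties to the
    earlier element).  Returns the two per-bin value arrays (one per marker
    axis).
    """
    k = len(seq.cells)
    if n_bins < k:
        raise ValueError(f"{n_bins} bins cannot hold {k} sequence elements")
    p = np.asarray(seq.proportions, dtype=float)
    if p.sum() > 1.0 + 1e-9:
        raise ValueError("sequence proportions sum to more than 1")
    quota = p * n_bins
    base = np.floor(quota).astype(int)
    remainder = n_bins - base.sum()
    frac = quota - base
    order = sorted(range(k), key=lambda i: (-frac[i], i))
    for i in order[:remainder]:
        base[i] += 1
    v1 = np.repeat([c[0] for c in seq.cells], base)
    v2 = np.repeat([c[1] for c in seq.cells], base)
    return v1.astype(float), v2.astype(float)


def _average_images(pair, mouse, trajectories, n_bins) -> Couple:
    """Per-mouse average of per-image trajectories.

    E2F axes average arithmetically; state axes take a per-bin majority vote
    (ties to the earlier state in temporal order, i.e. the smaller code).
    """
    members = []
    for axis, marker in enumerate(pair):
        stack = np.stack([t[axis] for t in trajectories])
        if is_e2f(marker):
            members.append(stack.mean(axis=0))
        else:
            votes = np.zeros((3, n_bins))
            for code in range(3):
                votes[code] = (stack == code).sum(axis=0)
            members.append(votes.argmax(axis=0).astype(float))
    return Couple(pair, mouse, members[0], members[1])


def initialize_all(
    levels: pd.DataFrame,
    combos,
    n_bins: int = 100,
    n_levels: int = 3,
    max_splits: int = 3,
    max_forbidden: int = 0,
) -> dict:
    """Initial trajectory couples for every (marker pair, mouse).

    Runs quantized-level histograms through the graph search image by image
    and averages each mouse's images.  When ``max_forbidden > 0``, images whose
    strict search is infeasible (degenerate histograms, e.g. from simultaneous
    level/state switches) are retried with relaxed forbidden-transition
    budgets; an image that still fails is skipped if the mouse has other
    images, and raises otherwise.
    """
    image_channels = levels.groupby("image")["channel"].agg(lambda s: frozenset(s))
    image_mouse = levels.groupby("image")["mouse"].first()
    out: dict = {}
    for pair in combos:
        wanted = frozenset(pair)
        images = [img for img, chans in image_channels.items() if wanted <= chans]
        by_mouse = groupby(
            sorted(images, key=lambda im: (image_mouse[im], im)),
            key=lambda im: image_mouse[im],
        )
        for mouse, imgs in by_mouse:
            trajectories = []
            errors = []
            for image in imgs:
                hist = joint_histogram(levels, pair, image, n_levels=n_levels)
                graph = build_graph(hist)
                try:
                    seq = min_cost_sequence(graph, max_splits=max_splits)
                except NoCoveringSequenceError as exc:
                    if max_forbidden > 0:
                        try:
                            seq = min_cost_sequence(
                                graph, max_splits=max_splits,
                                max_forbidden=max_forbidden,
                            )
                        except NoCoveringSequenceError as exc2:
                            errors.append((image, exc2))
                            continue
                    else:
                        errors.append((image, exc))
                        continue
                trajectories.append(sequence_to_trajectory(seq, n_bins))
            if not trajectories:
                raise NoCoveringSequenceError(
                    f"no image of mouse {mouse} admits a covering sequence for "
                    f"{pair}: {errors[0][1] if errors else 'no images'}"
                )
            out[(pair, int(mouse))] = _average_images(
                pair, int(mouse), trajectories, n_bins
            )
    return out
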