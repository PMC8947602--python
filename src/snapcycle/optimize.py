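"""Global refinement of trajectories as iterated assignment problems.

After registration the EdU/pH3 state sequences are fixed up to permutations
within a state, while E2F levels should agree across mice and across the
couples that share a marker.  Each couple is refined by solving a B x B
linear assignment problem whose cost couples the mouse's trajectory to every
reference trajectory sharing a marker, adds a large finite barrier against
moving a bin across an EdU/pH3 state boundary, and adds a circular locality
penalty d(c1, c2)^2 / z that loosens as the iteration z grows.  Five
minimization groups (one per E2F against its EdU/pH3 couples, then the two
E2F-E2F couples) are processed in order for z = 1..B; each is solved with the
Hungarian algorithm.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import splev, splrep
from scipy.optimize import linear_sum_assignment

from .markers import Couple, TrajectorySet

__all__ = [
    "hungarian",
    "circular_distance_sq",
    "build_cost_em",
    "build_cost_ee",
    "global_optimize",
    "fit_profile",
    "CyclicProfile",
]

_TRIPLES = {
    "E2F3A": ("E2F8", "E2F4"),
    "E2F8": ("E2F3A", "E2F4"),
    "E2F4": ("E2F8", "E2F3A"),
}
_EE_PAIRS = (("E2F3A", "E2F8"), ("E2F3A", "E2F4"))


def hungarian(cost: np.ndarray) -> np.ndarray:
    """Minimum-cost assignment of rows to columns; returns perm with col[row].

    Thin wrapper over the Jonker-Volgenant solver in scipy (the classical
    Hungarian algorithm's modern replacement); requires a square finite
    matrix.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square")
    if not np.isfinite(cost).all():
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(cost.shape[0], dtype=int)
    perm[rows] = cols
    return perm


def circular_distance_sq(n_bins: int) -> np.ndarray:
    """Matrix of squared circular bin distances d(c1, c2)^2."""
    c = np.arange(n_bins)
    d = np.abs(c[:, None] - c[None, :])
    d = np.minimum(d, n_bins - d)
    return (d**2).astype(float)


def _sq_outer(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(x(c1) - y(c2))^2 as a (B, B) matrix."""
    return (x[:, None] - y[None, :]) ** 2


def _barrier(states: np.ndarray, data_cost: np.ndarray) -> np.ndarray:
    """Large finite barrier where the state at c1 differs from the state at c2."""
    big = 1.0e6 * (float(np.max(data_cost)) + 1.0)
    return big * (states[:, None] != states[None, :])


def build_cost_em(
    trajectories: TrajectorySet,
    mouse: int,
    pair: tuple[str, str],
    z: int,
    d2: np.ndarray | None = None,
) -> np.ndarray:
    """Assignment cost for an E2F x EdU/pH3 couple at iteration ``z``.

    Entry (c1, c2) is the squared distance of the couple's E2F value at c1 to
    every same-genotype reference at c2 (the other state-marker couples and
    the existing cross-E2F couples), plus the state barrier keeping the
    mouse's own EdU/pH3 state at c1 equal to the state at c2, plus the
    circular locality penalty divided by z.
    """
    g1, m1 = pair
    m2 = "pH3" if m1 == "EdU" else "EdU"
    couple = trajectories[pair, mouse]
    x = couple.member(g1)
    cost = np.zeros((couple.n_bins, couple.n_bins))
    for j in trajectories.mice(g1):
        cost += _sq_outer(x, trajectories[(g1, m2), j].member(g1))
    for g_other in _TRIPLES[g1]:
        for ee in _EE_PAIRS:
            if set(ee) == {g1, g_other}:
                for j in range(min(len(trajectories.mice(g1)),
                                   len(trajectories.mice(g_other)))):
                    cost += _sq_outer(x, trajectories[ee, j].member(g1))
    states = couple.member(m1)
    cost += _barrier(states, cost)
    if d2 is None:
        d2 = circular_distance_sq(couple.n_bins)
    return cost + d2 / z


def build_cost_ee(
    trajectories: TrajectorySet,
    mouse: int,
    pair: tuple[str, str],
    z: int,
    d2: np.ndarray | None = None,
) -> np.ndarray:
    """Assignment cost for an E2F3A x other-E2F couple at iteration ``z``.

    Both members are compared against their genotypes' EdU and pH3 couples,
    plus the remaining cross-E2F couple, plus the locality penalty; no state
    barrier applies because neither axis carries a state.
    """
    g0, g1 = pair  # g0 is E2F3A
    couple = trajectories[pair, mouse]
    a, b = couple.member(g0), couple.member(g1)
    cost = np.zeros((couple.n_bins, couple.n_bins))
    for j in trajectories.mice(g0):
        cost += _sq_outer(a, trajectories[(g0, "EdU"), j].member(g0))
        cost += _sq_outer(a, trajectories[(g0, "pH3"), j].member(g0))
    for j in trajectories.mice(g1):
        cost += _sq_outer(b, trajectories[(g1, "EdU"), j].member(g1))
        cost += _sq_outer(b, trajectories[(g1, "pH3"), j].member(g1))
    (g2,) = [g for g in _TRIPLES[g0] if g != g1]
    other = tuple(p for p in _EE_PAIRS if set(p) == {g0, g2})
    if other:
        ee = other[0]
        for j in range(min(len(trajectories.mice(g0)), len(trajectories.mice(g2)))):
            cost += _sq_outer(a, trajectories[ee, j].member(g0))
    if d2 is None:
        d2 = circular_distance_sq(couple.n_bins)
    return cost + d2 / z


def _apply_permutation(couple: Couple, perm: np.ndarray) -> Couple:
    """New value at bin perm[c1] is the old value at bin c1, for both members."""
    a = np.empty_like(couple.a)
    b = np.empty_like(couple.b)
    a[perm] = couple.a
    b[perm] = couple.b
    return Couple(couple.pair, couple.mouse, a, b)


def global_optimize(
    registered: TrajectorySet,
    n_iters: int | None = None,
    callback=None,
) -> TrajectorySet:
    """Iterated Hungarian refinement of all couples.

    For each iteration z = 1..n_iters (default: the bin count B), the five
    minimization groups are processed in order: (E2F3A, EdU then pH3),
    (E2F8, EdU then pH3), (E2F4, EdU then pH3), then the E2F3A-E2F8 and
    E2F3A-E2F4 couples; each solve permutes that mouse's couple in place.
    ``callback(z, trajectories)`` runs after each iteration if given.
    """
    out = registered.copy()
    some = next(iter(out.couples.values()))
    n_bins = some.n_bins
    if n_iters is None:
        n_iters = n_bins
    d2 = circular_distance_sq(n_bins)
    for z in range(1, n_iters + 1):
        for g1 in ("E2F3A", "E2F8", "E2F4"):
            for m1 in ("EdU", "pH3"):
                for i in out.mice(g1):
                    if ((g1, m1), i) not in out:
                        continue
                    cost = build_cost_em(out, i, (g1, m1), z, d2)
                    perm = hungarian(cost)
                    out[(g1, m1), i] = _apply_permutation(out[(g1, m1), i], perm)
        for pair in _EE_PAIRS:
            g0, g1 = pair
            n_pair = min(len(out.mice(g0)), len(out.mice(g1)))
            for i in range(n_pair):
                if (pair, i) not in out:
                    continue
                cost = build_cost_ee(out, i, pair, z, d2)
                perm = hungarian(cost)
                out[pair, i] = _apply_permutation(out[pair, i], perm)
        if callback is not None:
            callback(z, out)
    return out


class CyclicProfile:
    """Smooth periodic concentration profile of one E2F over the cycle."""

    def __init__(self, marker: str, tck, n_bins: int):
        self.marker = marker
        self.tck = tck
        self.n_bins = n_bins

    @property
    def values(self) -> np.ndarray:
        v = splev(np.arange(self.n_bins, dtype=float), self.tck)
        return np.maximum(np.asarray(v), 0.0)

    def __call__(self, c) -> np.ndarray:
        return np.maximum(np.asarray(splev(np.asarray(c, float) % self.n_bins,
                                           self.tck)), 0.0)


def fit_profile(
    trajectories: TrajectorySet, marker: str, smoothing: float | None = None
) -> CyclicProfile:
    """Periodic cubic smoothing spline through the pooled marker trajectories.

    All sequences of ``marker`` across mice and couples are pooled; the spline
    is fitted to the per-bin means with periodic boundary conditions and
    clamped at zero.  ``smoothing=None`` picks the between-mouse residual sum
    of squares around the bin means (so the fit does not chase inter-mouse
    noise); ``smoothing=0`` interpolates the bin means exactly.
    """
    pool = [
        c.member(marker) for (pair, _), c in trajectories.items() if marker in pair
    ]
    if not pool:
        raise ValueError(f"no trajectory involves {marker}")
    stack = np.stack(pool)
    means = stack.mean(axis=0)
    if smoothing is None:
        smoothing = float(((stack - means) ** 2).sum()) / stack.shape[0]
    n_bins = means.size
    x = np.arange(n_bins + 1, dtype=float)
    y = np.r_[means, means[0]]
    tck = splrep(x, y, per=1, s=smoothing)
    return CyclicProfile(marker, tck, n_bins)
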