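"""Circular registration of trajectory couples to the cell-cycle anchors.

pH3 is diffuse during mitosis, which ends the cycle: every couple containing
pH3 is rotated so its diffuse run ends at the last bin, and those anchored
sequences become the references.  EdU-linked couples are then registered by
exhaustive search over circular shifts minimizing the summed squared distance
of their E2F member to the corresponding pH3-anchored references, refined with
cross-mouse EdU-consistency terms; E2F-E2F couples are registered against the
pH3 references of both their markers.  All distances on state sequences use
the ordinal codes (temporal order).
"""

from __future__ import annotations

import numpy as np

from .markers import Couple, E2F_MARKERS, TrajectorySet

__all__ = [
    "anchor_ph3",
    "best_shift",
    "register_to_ph3",
    "refine_edu",
    "register_all",
]

#: successive genotype triples used by the EdU refinement pass
_TRIPLES = (
    ("E2F3A", "E2F8", "E2F4"),
    ("E2F8", "E2F3A", "E2F4"),
    ("E2F4", "E2F8", "E2F3A"),
)

_DIFFUSE = 2  # ordinal code of the diffuse pattern for pH3


def anchor_ph3(couple: Couple) -> tuple[Couple, int]:
    """Rotate a pH3-containing couple so the diffuse run ends the cycle.

    Returns the rotated couple and the applied shift.  The pH3 axis must
    contain at least one diffuse bin; an all-diffuse sequence is a degenerate
    anchor and is returned unchanged.
    """
    if "pH3" not in couple.pair:
        raise ValueError("couple has no pH3 axis")
    states = couple.member("pH3")
    diffuse = states == _DIFFUSE
    if not diffuse.any():
        raise ValueError("cannot anchor: pH3 axis has no diffuse bin")
    if diffuse.all():
        return couple, 0
    # last bin of the single circular diffuse run: the diffuse bin whose
    # circular successor is not diffuse
    n = states.size
    run_end = int(np.flatnonzero(diffuse & ~np.roll(diffuse, -1))[0])
    q = (n - 1 - run_end) % n
    return couple.shifted(q), q


def _anchor_with_fallback(couple: Couple) -> tuple[Couple, int]:
    """Anchor on the diffuse run end, falling back to the punctate run end.

    A sampled trajectory can miss the (short) mitotic diffuse run entirely;
    the end of the punctate run is the next-best proxy for the end of the
    cycle.  With neither pattern present the couple is left unshifted.
    """
    try:
        return anchor_ph3(couple)
    except ValueError:
        states = couple.member("pH3")
        punctate = states == 1
        if not punctate.any() or punctate.all():
            return couple, 0
        n = states.size
        run_end = int(np.flatnonzero(punctate & ~np.roll(punctate, -1))[0])
        q = (n - 1 - run_end) % n
        return couple.shifted(q), q


def best_shift(candidate: np.ndarray, objective) -> int:
    """Smallest circular shift minimizing ``objective(shifted candidate)``."""
    n = candidate.size
    values = np.array([objective(np.roll(candidate, q)) for q in range(n)])
    return int(np.argmin(values))  # argmin returns the first (smallest) q


def _sq(a: np.ndarray, b: np.ndarray) -> float:
    return float(((a - b) ** 2).sum())


def register_to_ph3(couple: Couple, references: list[np.ndarray]) -> tuple[Couple, int]:
    """Shift an EdU couple to match the pH3-anchored E2F references.

    ``references`` are the anchored ``X_j^{G-pH3}`` E2F member sequences of
    all mice of the genotype; the couple's E2F member is compared at every
    circular shift and both members are shifted by the minimizer (smallest
    shift on ties).
    """
    g = couple.pair[0]
    cand = couple.member(g)
    q = best_shift(cand, lambda x: sum(_sq(x, ref) for ref in references))
    return couple.shifted(q), q


def refine_edu(trajectories: TrajectorySet) -> dict:
    """Second registration pass on the EdU couples using E2F consistency.

    For each genotype triple (G1, G2, G3), each mouse's (G1, EdU) couple is
    re-shifted to minimize the sum of its distance to the G1-pH3 references
    plus the distances of its EdU state member to the other genotypes' EdU
    state members.  Updates are applied in the listed triple order and
    reference the current (partially updated) set.  Returns the extra shifts.
    """
    shifts: dict = {}
    for g1, g2, g3 in _TRIPLES:
        ph3_refs = [
            trajectories[(g1, "pH3"), j].member(g1) for j in trajectories.mice(g1)
        ]
        for i in trajectories.mice(g1):
            couple = trajectories[(g1, "EdU"), i]
            edu_refs = [
                trajectories[(g, "EdU"), j].member("EdU")
                for g in (g2, g3)
                for j in trajectories.mice(g)
            ]
            e2f = couple.member(g1)
            edu = couple.member("EdU")

            def objective(q: int) -> float:
                se = sum(_sq(np.roll(e2f, q), ref) for ref in ph3_refs)
                ss = sum(_sq(np.roll(edu, q), ref) for ref in edu_refs)
                return se + ss

            values = [objective(q) for q in range(couple.n_bins)]
            q = int(np.argmin(values))
            trajectories[(g1, "EdU"), i] = couple.shifted(q)
            shifts[((g1, "EdU"), i)] = q
    return shifts


def _register_e2f_pair(trajectories: TrajectorySet, pair: tuple[str, str]) -> dict:
    """Shift an E2F-E2F couple against both markers' pH3 references."""
    g1, g2 = pair
    shifts: dict = {}
    refs1 = [trajectories[(g1, "pH3"), j].member(g1) for j in trajectories.mice(g1)]
    refs2 = [trajectories[(g2, "pH3"), j].member(g2) for j in trajectories.mice(g2)]
    n_pair = min(len(trajectories.mice(g1)), len(trajectories.mice(g2)))
    for i in range(n_pair):
        couple = trajectories[pair, i]
        a, b = couple.member(g1), couple.member(g2)

        def objective(q: int) -> float:
            return sum(_sq(np.roll(a, q), r) for r in refs1) + sum(
                _sq(np.roll(b, q), r) for r in refs2
            )

        values = [objective(q) for q in range(couple.n_bins)]
        q = int(np.argmin(values))
        trajectories[pair, i] = couple.shifted(q)
        shifts[(pair, i)] = q
    return shifts


def register_all(initial: dict, nb_s: int, nb_s2: int) -> tuple[TrajectorySet, dict]:
    """Register every initialized couple to the cell-cycle anchors.

    ``initial`` maps (pair, mouse) to couples as produced by
    ``initialize_all``.  Returns the registered set and the applied shifts.
    """
    out = TrajectorySet(nb_s, nb_s2, {k: c.copy() for k, c in initial.items()})
    shifts: dict = {}
    for g in E2F_MARKERS:
        for i in out.mice(g):
            if ((g, "pH3"), i) in out:
                anchored, q = _anchor_with_fallback(out[(g, "pH3"), i])
                out[(g, "pH3"), i] = anchored
                shifts[((g, "pH3"), i)] = q
    for g in E2F_MARKERS:
        refs = [out[(g, "pH3"), j].member(g) for j in out.mice(g)]
        for i in out.mice(g):
            if ((g, "EdU"), i) in out:
                shifted, q = register_to_ph3(out[(g, "EdU"), i], refs)
                out[(g, "EdU"), i] = shifted
                shifts[((g, "EdU"), i)] = q
    extra = refine_edu(out)
    for key, q in extra.items():
        shifts[key] = (shifts.get(key, 0) + q) % out[key].n_bins
    for pair in (("E2F3A", "E2F8"), ("E2F3A", "E2F4")):
        if any(k[0] == pair for k in out.couples):
            shifts.update(_register_e2f_pair(out, pair))
    return out, shifts
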