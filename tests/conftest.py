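"""Shared fixtures: worked-example histograms and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snapcycle.markers import COMBOS, Couple, TrajectorySet, combo_mice
from snapcycle.quantize import JointHistogram
from snapcycle.simulate import SimulationSpec, simulate_dataset

#: the nine non-zero cells of the published E2F3A x pH3 example histogram,
#: (E2F3A level, pH3 state code) -> count per 100 nuclei; only the 34% cell
#: is published, the rest are positive stand-ins (edge costs ignore counts)
WORKED_CELLS = {
    (0, 0): 10,
    (1, 0): 12,
    (2, 0): 34,
    (3, 0): 8,
    (3, 1): 6,
    (2, 1): 9,
    (1, 1): 7,
    (0, 1): 6,
    (0, 2): 8,
}

#: the published minimum-cost traversal of that histogram
WORKED_SEQUENCE = [
    (0, 0), (1, 0), (2, 0), (3, 0), (3, 1), (2, 1), (1, 1), (0, 1), (0, 2)
]


@pytest.fixture
def worked_histogram() -> JointHistogram:
    counts = np.zeros((4, 3), dtype=int)
    for cell, c in WORKED_CELLS.items():
        counts[cell] = c
    return JointHistogram(("E2F3A", "pH3"), counts, counts.sum())


@pytest.fixture
def small_truth():
    return simulate_dataset(SimulationSpec(nb_i=4, nb_t=100, nb_s=3, nb_s2=2, seed=11))


def consistent_trajectory_set(seed: int, n_bins: int = 100) -> TrajectorySet:
    """A mutually consistent couple set: all mice share one sample's truth.

    Every couple of every mouse is built directly from the same underlying
    simulated sample, so after anchoring all couples agree bin for bin.
    """
    truth = simulate_dataset(
        SimulationSpec(nb_i=4, nb_t=n_bins, nb_s=1, nb_s2=1, seed=seed)
    )
    seqs = {m: truth.sequences[m][0].astype(float) for m in truth.sequences}
    ts = TrajectorySet(3, 2)
    for pair in COMBOS:
        for i in range(combo_mice(pair, 3, 2)):
            ts[pair, i] = Couple(pair, i, seqs[pair[0]].copy(), seqs[pair[1]].copy())
    return ts
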