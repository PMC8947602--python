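"""Marker alphabets, state encodings and the eight marker couples.

Three E2F transcription factors are profiled (E2F3A, an activator; E2F8, an
atypical repressor; E2F4, a canonical repressor) together with two cell-cycle
anchors: EdU (S-phase label, diffuse in the first half of S then punctate) and
pH3 (phospho-histone H3, punctate in late S/G2 then diffuse in mitosis).

E2F channels carry quantized intensity levels (integers, 0 = negative).
EdU/pH3 channels carry a categorical pattern; everywhere in this package the
patterns are encoded ordinally in each marker's *temporal* order::

    EdU:  negative=0, diffuse=1, punctate=2
    pH3:  negative=0, punctate=1, diffuse=2

which is also the order of the axis in joint histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

E2F_MARKERS = ("E2F3A", "E2F8", "E2F4")
STATE_MARKERS = ("EdU", "pH3")

#: state name -> ordinal code, per marker, in temporal order.  "positive" is
#: the marker-identification-free variant (no diffuse/punctate calls): it maps
#: onto the first active slot, so a positive run still anchors the cycle (for
#: pH3 via the punctate-run fallback).
STATE_CODES = {
    "EdU": {"negative": 0, "diffuse": 1, "punctate": 2, "positive": 1},
    "pH3": {"negative": 0, "punctate": 1, "diffuse": 2, "positive": 1},
}
STATE_NAMES = {
    m: {v: k for k, v in d.items() if k != "positive"}
    for m, d in STATE_CODES.items()
}

#: The eight marker couples reconstructed by the pipeline, (M1, M2) with the
#: E2F (genotype) axis first for E2F x EdU/pH3 couples.
COMBOS = (
    ("E2F3A", "EdU"),
    ("E2F3A", "pH3"),
    ("E2F8", "EdU"),
    ("E2F8", "pH3"),
    ("E2F4", "EdU"),
    ("E2F4", "pH3"),
    ("E2F3A", "E2F8"),
    ("E2F3A", "E2F4"),
)


def is_e2f(marker: str) -> bool:
    return marker in E2F_MARKERS


def is_state(marker: str) -> bool:
    return marker in STATE_MARKERS


def n_mice(marker: str, nb_s: int, nb_s2: int) -> int:
    """Number of samples (mice) available for a marker: ``nb_s2`` for E2F4."""
    return nb_s2 if marker == "E2F4" else nb_s


def combo_mice(combo: tuple[str, str], nb_s: int, nb_s2: int) -> int:
    """A couple exists only for mice that have both markers."""
    return min(n_mice(combo[0], nb_s, nb_s2), n_mice(combo[1], nb_s, nb_s2))


@dataclass
class Couple:
    """One couple of aligned marker sequences over B circular time bins.

    ``a`` holds the values of ``pair[0]`` and ``b`` the values of ``pair[1]``,
    bin for bin (bin c of ``a`` and of ``b`` describe the same cell-cycle
    time).  E2F members are real-valued after per-mouse averaging; state
    members hold ordinal codes.
    """

    pair: tuple[str, str]
    mouse: int
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("couple members must be 1-D arrays of equal length")

    @property
    def n_bins(self) -> int:
        return self.a.size

    def member(self, marker: str) -> np.ndarray:
        """Sequence of ``marker`` within this couple (X^{marker-other})."""
        if marker == self.pair[0]:
            return self.a
        if marker == self.pair[1]:
            return self.b
        raise KeyError(f"{marker!r} not in couple {self.pair}")

    def shifted(self, q: int) -> "Couple":
        """Both members circularly shifted forward by ``q`` bins."""
        return Couple(self.pair, self.mouse, np.roll(self.a, q), np.roll(self.b, q))

    def copy(self) -> "Couple":
        return Couple(self.pair, self.mouse, self.a.copy(), self.b.copy())


@dataclass
class TrajectorySet:
    """All couples of a dataset, keyed by (pair, mouse), plus sample counts."""

    nb_s: int
    nb_s2: int
    couples: dict = field(default_factory=dict)

    def __getitem__(self, key) -> Couple:
        return self.couples[key]

    def __setitem__(self, key, value: Couple) -> None:
        self.couples[key] = value

    def __contains__(self, key) -> bool:
        return key in self.couples

    def get(self, pair: tuple[str, str], mouse: int) -> Couple | None:
        return self.couples.get((pair, mouse))

    def mice(self, marker: str) -> range:
        return range(n_mice(marker, self.nb_s, self.nb_s2))

    def items(self):
        return self.couples.items()

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            self.nb_s, self.nb_s2, {k: c.copy() for k, c in self.couples.items()}
        )
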