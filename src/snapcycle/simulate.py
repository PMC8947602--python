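"""Synthetic data: simulated marker trajectories, corruption, MSE scoring,
per-nucleus measurement tables and score-map image fixtures.

The simulator emulates an asynchronously cycling cell population observed in
fixed snapshots.  Per sample (mouse), each activating/atypical E2F
concentration is a single circular wave of quantized intensity (stepwise rise
from 0 to ``nb_i`` and back), E2F4 shows two such waves, and the EdU/pH3
pattern sequences follow their known cell-cycle order (EdU: diffuse then
punctate during S; pH3: punctate in late S/G2 then diffuse in mitosis, starting
after EdU).  Run durations are drawn uniformly on integers ``[1, D_max]`` with
``D_max = floor(2*nb_t / (3*nb_i))`` for single waves and EdU/pH3 pattern runs
and ``floor(nb_t / (3*nb_i))`` per level for each E2F4 wave, which guarantees a
single wave is shorter than the cycle and both E2F4 waves fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import COMBOS, E2F_MARKERS, STATE_NAMES, combo_mice, is_e2f

__all__ = [
    "SimulationSpec",
    "SimulatedTruth",
    "MseReport",
    "SimulationError",
    "simulate_dataset",
    "corrupt",
    "evaluate_mse",
    "aggregate_mse",
    "sample_nucleus_table",
    "make_score_maps",
]

_MAX_TRIES = 10_000


class SimulationError(ValueError):
    """A simulation spec that cannot satisfy the trajectory invariants."""


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated dataset.

    ``nb_i`` is the number of positive intensity levels (levels run 0..nb_i),
    ``nb_t`` the number of circular time bins, ``nb_s`` the number of samples
    (mice) for E2F3A/E2F8/EdU/pH3 and ``nb_s2`` the number for E2F4.
    """

    nb_i: int = 4
    nb_t: int = 100
    nb_s: int = 3
    nb_s2: int = 2
    noise_fraction: float = 0.0
    seed: int = 0
    replicate_count: int = 5

    def __post_init__(self) -> None:
        if self.nb_i < 1:
            raise SimulationError("nb_i must be >= 1")
        if self.nb_t < 2 * (self.nb_i + 1):
            raise SimulationError("nb_t must be >= 2*(nb_i+1)")
        if self.nb_s < 1 or self.nb_s2 < 1:
            raise SimulationError("sample counts must be >= 1")
        if not 0.0 <= self.noise_fraction <= 0.5:
            raise SimulationError("noise_fraction must lie in [0, 0.5]")


@dataclass
class SimulatedTruth:
    """Ground-truth level/state sequences, one row per sample.

    ``sequences[marker]`` is an int array of shape ``(n_samples, nb_t)``;
    E2F values are levels in {0..nb_i}, EdU/pH3 values are ordinal state codes
    in each marker's temporal order.
    """

    nb_i: int
    nb_t: int
    sequences: dict[str, np.ndarray] = field(default_factory=dict)

    def n_samples(self, marker: str) -> int:
        return self.sequences[marker].shape[0]

    def copy(self) -> "SimulatedTruth":
        return SimulatedTruth(
            self.nb_i, self.nb_t, {m: y.copy() for m, y in self.sequences.items()}
        )


def _single_wave_dmax(nb_i: int, nb_t: int) -> int:
    return (2 * nb_t) // (3 * nb_i)


def _place_runs(seq: np.ndarray, start: int, values, durations) -> int:
    """Write consecutive runs into a circular sequence; returns the end bin."""
    pos = start
    for v, d in zip(values, durations):
        idx = (pos + np.arange(d)) % seq.size
        seq[idx] = v
        pos += d
    return pos % seq.size


def _wave_profile(nb_i: int) -> list[int]:
    """Level order of one concave wave: 1..nb_i..1 (2*nb_i - 1 runs)."""
    return list(range(1, nb_i + 1)) + list(range(nb_i - 1, 0, -1))


def _single_wave(rng: np.random.Generator, nb_i: int, nb_t: int) -> np.ndarray:
    dmax = _single_wave_dmax(nb_i, nb_t)
    n_runs = 2 * nb_i - 1
    if dmax < 1 or n_runs + 1 > nb_t:
        raise SimulationError(
            "nb_t too small for a single concave wave with at least one zero bin"
        )
    for _ in range(_MAX_TRIES):
        durations = rng.integers(1, dmax + 1, size=n_runs)
        if durations.sum() <= nb_t - 1:
            break
    else:  # pragma: no cover - astronomically unlikely for valid specs
        raise SimulationError("could not draw wave durations shorter than the cycle")
    seq = np.zeros(nb_t, dtype=int)
    start = int(rng.integers(0, nb_t))
    _place_runs(seq, start, _wave_profile(nb_i), durations)
    return seq


def _double_wave(rng: np.random.Generator, nb_i: int, nb_t: int) -> np.ndarray:
    dmax = nb_t // (3 * nb_i)
    n_runs = 2 * nb_i - 1
    if dmax < 1 or 2 * n_runs + 2 > nb_t:
        raise SimulationError(
            "nb_t too small to place both E2F4 waves with separating zero bins"
        )
    for _ in range(_MAX_TRIES):
        d1 = rng.integers(1, dmax + 1, size=n_runs)
        d2 = rng.integers(1, dmax + 1, size=n_runs)
        if d1.sum() + d2.sum() + 2 <= nb_t:
            break
    else:  # pragma: no cover
        raise SimulationError("could not fit both E2F4 waves in the cycle")
    seq = np.zeros(nb_t, dtype=int)
    length1, length2 = int(d1.sum()), int(d2.sum())
    start1 = int(rng.integers(0, nb_t))
    end1 = _place_runs(seq, start1, _wave_profile(nb_i), d1)
    # the second wave starts after the first ends, with >= 1 zero bin on each side
    gap1 = int(rng.integers(1, nb_t - length1 - length2 - 1 + 1))
    _place_runs(seq, (end1 + gap1) % nb_t, _wave_profile(nb_i), d2)
    return seq


def _state_pair(
    rng: np.random.Generator, nb_i: int, nb_t: int
) -> tuple[np.ndarray, np.ndarray]:
    """EdU and pH3 sequences for one sample; pH3 starts after EdU."""
    dmax = _single_wave_dmax(nb_i, nb_t)
    if dmax < 1 or nb_t < 5:
        raise SimulationError("nb_t too small for EdU/pH3 pattern runs")
    for _ in range(_MAX_TRIES):
        edu_runs = rng.integers(1, dmax + 1, size=2)  # diffuse, punctate
        ph3_runs = rng.integers(1, dmax + 1, size=2)  # punctate, diffuse
        len_e, len_p = int(edu_runs.sum()), int(ph3_runs.sum())
        if len_e + len_p + 1 > nb_t:
            continue
        start_e = int(rng.integers(0, nb_t - len_e + 1))
        if start_e + 1 > nb_t - len_p:
            continue
        start_p = int(rng.integers(start_e + 1, nb_t - len_p + 1))
        break
    else:  # pragma: no cover
        raise SimulationError("could not place EdU/pH3 pattern runs")
    edu = np.zeros(nb_t, dtype=int)
    ph3 = np.zeros(nb_t, dtype=int)
    _place_runs(edu, start_e, [1, 2], edu_runs)
    _place_runs(ph3, start_p, [1, 2], ph3_runs)
    return edu, ph3


def simulate_dataset(spec: SimulationSpec) -> SimulatedTruth:
    """Generate ground-truth trajectories for one simulated dataset.

    Deterministic given ``spec.seed``.  Raises :class:`SimulationError` if the
    spec cannot satisfy the trajectory invariants (e.g. ``nb_t`` too small to
    place both E2F4 waves).
    """
    rng = np.random.default_rng(spec.seed)
    nb_i, nb_t = spec.nb_i, spec.nb_t
    y3a = np.stack([_single_wave(rng, nb_i, nb_t) for _ in range(spec.nb_s)])
    y8 = np.stack([_single_wave(rng, nb_i, nb_t) for _ in range(spec.nb_s)])
    states = [_state_pair(rng, nb_i, nb_t) for _ in range(spec.nb_s)]
    yedu = np.stack([s[0] for s in states])
    yph3 = np.stack([s[1] for s in states])
    y4 = np.stack([_double_wave(rng, nb_i, nb_t) for _ in range(spec.nb_s2)])
    return SimulatedTruth(
        nb_i,
        nb_t,
        {"E2F3A": y3a, "E2F8": y8, "E2F4": y4, "EdU": yedu, "pH3": yph3},
    )


def _alphabet_size(marker: str, nb_i: int) -> int:
    return nb_i + 1 if is_e2f(marker) else 3


def corrupt(truth: SimulatedTruth, noise_fraction: float, seed: int) -> SimulatedTruth:
    """Replace exactly ``round(noise_fraction * nb_t)`` bins per sequence.

    Each corrupted bin receives a uniform draw over the *other* admissible
    values (never the true one), so the requested fraction equals the realized
    corruption rate.
    """
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError("noise_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = truth.copy()
    k = int(round(noise_fraction * truth.nb_t))
    for marker, y in out.sequences.items():
        n_values = _alphabet_size(marker, truth.nb_i)
        for j in range(y.shape[0]):
            bins = rng.choice(truth.nb_t, size=k, replace=False)
            # uniform over the n_values-1 wrong values via an offset draw
            offsets = rng.integers(1, n_values, size=k)
            y[j, bins] = (y[j, bins] + offsets) % n_values
    return out


@dataclass
class MseReport:
    """Per-marker mean squared error after the best circular alignment."""

    per_marker: dict[str, float]
    shifts: dict

    def __getitem__(self, marker: str) -> float:
        return self.per_marker[marker]


def evaluate_mse(
    estimate: dict[str, np.ndarray],
    truth: SimulatedTruth,
    alignment: str = "marker",
) -> MseReport:
    """MSE between estimated and true sequences, per marker.

    The absolute cycle phase is unidentifiable from snapshots and every
    simulated sample (mouse) carries its own arbitrary phase, while the
    reconstruction registers all samples to a common anchor, so a circular
    shift of the estimates is searched exhaustively before scoring.  With
    ``alignment="marker"`` (default) each marker-and-sample sequence is
    aligned on its own, matching a per-marker error evaluation; with
    ``alignment="sample"`` one shift per sample is shared by all of that
    sample's markers, additionally penalizing phase incoherence between
    markers.  Estimate arrays may be 1-D (one consensus sequence, compared
    against every truth sample) or 2-D ``(n_samples, nb_t)``; EdU/pH3 must use
    ordinal state codes.
    """
    if alignment not in ("marker", "sample"):
        raise ValueError("alignment must be 'marker' or 'sample'")
    nb_t = truth.nb_t
    pairs = []
    for marker, est in estimate.items():
        est = np.atleast_2d(np.asarray(est, dtype=float))
        y = truth.sequences[marker].astype(float)
        if est.shape[1] != nb_t:
            raise ValueError(f"{marker}: estimate length {est.shape[1]} != {nb_t}")
        if est.shape[0] == 1 and y.shape[0] > 1:
            est = np.broadcast_to(est, y.shape)
        elif est.shape[0] != y.shape[0]:
            raise ValueError(f"{marker}: {est.shape[0]} estimates for {y.shape[0]} samples")
        pairs.append((marker, est, y))
    # per-(marker, sample) SSE for every candidate shift
    sse = {}
    for marker, est, y in pairs:
        grid = np.empty((y.shape[0], nb_t))
        for q in range(nb_t):
            grid[:, q] = ((np.roll(est, q, axis=1) - y) ** 2).sum(axis=1)
        sse[marker] = grid
    shifts: dict = {}
    per_marker: dict[str, float] = {}
    if alignment == "marker":
        for marker, _, y in pairs:
            qs = np.argmin(sse[marker], axis=1)
            shifts[marker] = [int(q) for q in qs]
            per_marker[marker] = float(
                sum(sse[marker][j, qs[j]] for j in range(y.shape[0])) / y.size
            )
    else:
        n_samples = max(y.shape[0] for _, _, y in pairs)
        sample_q = []
        for j in range(n_samples):
            total = np.zeros(nb_t)
            for marker, _, y in pairs:
                if j < y.shape[0]:
                    total += sse[marker][j]
            sample_q.append(int(np.argmin(total)))
        shifts["sample"] = sample_q
        for marker, _, y in pairs:
            tot = sum(sse[marker][j, sample_q[j]] for j in range(y.shape[0]))
            per_marker[marker] = float(tot / y.size)
    return MseReport(per_marker, shifts)


def aggregate_mse(reports: list[MseReport]) -> pd.DataFrame:
    """Mean +/- standard error of per-marker MSE across replicates."""
    df = pd.DataFrame([r.per_marker for r in reports])
    n = len(df)
    return pd.DataFrame(
        {"mean": df.mean(), "sem": df.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0}
    )


def sample_nucleus_table(
    truth: SimulatedTruth,
    cells_per_image: int,
    images_per_mouse: int,
    intensity_scale: float = 1000.0,
    seed: int = 0,
    combos: tuple = COMBOS,
    intensity_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Synthesize a per-nucleus measurement table from ground truth.

    Each synthetic nucleus is assigned a cell-cycle time uniform over the
    ``nb_t`` bins (an asynchronous population spends time in each state in
    proportion to its duration); its levels/states are read off the truth.
    Mean intensities are drawn so that per-image quantization with
    ``n_levels = nb_i`` recovers the assigned level: positive level ``l`` maps
    to ``scale * l`` (plus optional Gaussian noise), with a fresh scale per
    image; negative nuclei get sub-band intensity that may overlap the level-1
    band (the annotated state, not the intensity, makes them negative).
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for m1, m2 in combos:
        for mouse in range(combo_mice((m1, m2), truth.n_samples("E2F3A"),
                                      truth.n_samples("E2F4"))):
            for k in range(images_per_mouse):
                image = f"m{mouse}_{m1}-{m2}_i{k}"
                scale = intensity_scale * rng.uniform(0.5, 1.5)
                times = rng.integers(0, truth.nb_t, size=cells_per_image)
                for channel in (m1, m2):
                    values = truth.sequences[channel][mouse, times]
                    noise = (
                        rng.normal(0.0, intensity_noise_sd * scale, size=values.size)
                        if intensity_noise_sd > 0
                        else 0.0
                    )
                    if is_e2f(channel):
                        intensity = np.where(
                            values > 0,
                            scale * values + noise,
                            scale * rng.uniform(0.0, 0.8, size=values.size),
                        )
                        state = np.where(values > 0, "positive", "negative")
                    else:
                        intensity = np.where(
                            values > 0, scale + noise, scale * 0.05
                        )
                        names = STATE_NAMES[channel]
                        state = np.array([names[v] for v in values])
                    for e in range(cells_per_image):
                        rows.append(
                            (mouse, image, e, channel,
                             max(float(np.atleast_1d(intensity)[e]), 0.0), state[e])
                        )
    return pd.DataFrame(
        rows, columns=["mouse", "image", "nucleus", "channel", "mean_intensity", "state"]
    )


def make_score_maps(
    n_nuclei: int,
    image_size: int,
    touching: bool = False,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Render synthetic inner/contour class score maps plus ground-truth labels.

    Nuclei are disks with a bright inner-score core and a contour-score rim.
    With ``touching=True`` nuclei are laid out in pairs whose shared interface
    carries high contour score except for a small mis-scored bridge, so simple
    thresholding under-segments the pair while the corrected watershed can
    recover both nuclei.  Returns ``(ClassScoreMaps, label image)``.
    """
    from .watershed import ClassScoreMaps  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    shape = (image_size, image_size)
    s_n = np.zeros(shape, dtype=np.float32)
    s_c = np.zeros(shape, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint16)

    yy, xx = np.mgrid[0:image_size, 0:image_size]

    def disk_mask(cy, cx, r):
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    placed: list[tuple[float, float, float]] = []  # (cy, cx, r)
    pairs: list[tuple[int, int]] = []

    def far_enough(cy, cx, r, skip=()):
        for idx, (py, px, pr) in enumerate(placed):
            if idx in skip:
                continue
            if (py - cy) ** 2 + (px - cx) ** 2 < (pr + r + 6) ** 2:
                return False
        return True

    def place_one(r, skip=()):
        margin = r + 18 if touching else r + 3
        if image_size <= 2 * margin:
            raise ValueError("image_size too small for the requested nuclei")
        for _ in range(_MAX_TRIES):
            cy = rng.uniform(margin, image_size - margin)
            cx = rng.uniform(margin, image_size - margin)
            if far_enough(cy, cx, r, skip):
                return cy, cx
        raise ValueError("image_size too small for the requested nuclei")

    i = 0
    while i < n_nuclei:
        r1 = float(rng.integers(8, 13))
        if touching and i + 1 < n_nuclei:
            r2 = float(rng.integers(8, 13))
            cy1, cx1 = place_one(max(r1, r2) + r2 + 2)
            theta = rng.uniform(0, 2 * np.pi)
            d = r1 + r2 - 2.0
            cy2, cx2 = cy1 + d * np.sin(theta), cx1 + d * np.cos(theta)
            placed.extend([(cy1, cx1, r1), (cy2, cx2, r2)])
            pairs.append((i, i + 1))
            i += 2
        else:
            cy, cx = place_one(r1)
            placed.append((cy, cx, r1))
            i += 1

    from skimage.morphology import dilation as binary_dilation, erosion as binary_erosion, disk

    disks = [disk_mask(cy, cx, r) for cy, cx, r in placed]
    rim_selem = disk(2)
    interiors = []
    for idx, d_mask in enumerate(disks):
        interior = binary_erosion(d_mask, rim_selem)
        for jdx, other in enumerate(disks):
            if jdx != idx:
                interior &= ~binary_dilation(other, disk(1))
        interiors.append(interior)
        rim = d_mask & ~interior
        s_n[interior] = 1.0
        s_c[rim] = np.maximum(s_c[rim], 1.0)
        s_n[rim] = np.minimum(s_n[rim], 0.0)
        labels[interior] = idx + 1

    for i1, i2 in pairs:
        interface = binary_dilation(disks[i1], disk(1)) & binary_dilation(
            disks[i2], disk(1)
        )
        s_c[interface] = 0.8
        s_n[interface] = 0.2
        # a thin mis-scored strip along the centre-centre axis connects the two
        # interiors through the interface (the under-segmentation to correct)
        (cy1, cx1, _), (cy2, cx2, _) = placed[i1], placed[i2]
        my, mx = (cy1 + cy2) / 2.0, (cx1 + cx2) / 2.0
        vy, vx = cy2 - cy1, cx2 - cx1
        norm = float(np.hypot(vy, vx))
        uy, ux = vy / norm, vx / norm
        proj = (yy - my) * uy + (xx - mx) * ux
        perp = np.abs((yy - my) * ux - (xx - mx) * uy)
        bridge = (perp <= 1.5) & (np.abs(proj) <= 4.0) & (disks[i1] | disks[i2])
        s_n[bridge] = 0.9
        s_c[bridge] = 0.2

    if noise_sd > 0:
        s_n = s_n + rng.normal(0.0, noise_sd, shape).astype(np.float32)
        s_c = s_c + rng.normal(0.0, noise_sd, shape).astype(np.float32)

    return ClassScoreMaps(inner=s_n, contour=s_c), labels
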