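"""Readers/writers for the package's CSV/TIFF artifacts and the config schema.

Conventions: CSV files are UTF-8, comma-separated, with a mandatory header
row; time bins are 1-based and circular in files (0-based internally); pixel
coordinates are 0-based row-major.  Score maps are 32-bit float TIFF, label
images 16-bit unsigned TIFF.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .markers import Couple, TrajectorySet
from .simulate import SimulatedTruth

__all__ = [
    "PipelineConfig",
    "read_nucleus_table",
    "write_nucleus_table",
    "read_truth",
    "write_truth",
    "read_couples",
    "write_couples",
    "write_shifts",
    "read_score_map",
    "write_score_map",
    "read_labels",
    "write_labels",
]

_REQUIRED = ["mouse", "image", "nucleus", "channel", "mean_intensity", "state"]
_E2F_STATES = {"positive", "negative"}
# "positive" without a diffuse/punctate call is the marker-identification-free
# input variant
_PATTERN_STATES = {"negative", "diffuse", "punctate", "positive"}


def read_nucleus_table(path) -> pd.DataFrame:
    """Read and validate a per-nucleus measurement CSV.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers.  State labels are normalized to lower case.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    problems = []
    intensity = pd.to_numeric(df["mean_intensity"], errors="coerce")
    for idx in df.index[intensity.isna()]:
        problems.append(f"line {idx + 2}: non-numeric mean_intensity")
    for idx in df.index[intensity < 0]:
        problems.append(f"line {idx + 2}: negative mean_intensity")
    df["mean_intensity"] = intensity
    df["state"] = df["state"].astype(str).str.strip().str.lower()
    from .markers import is_e2f, is_state

    for idx, (channel, state) in df[["channel", "state"]].iterrows():
        if is_e2f(channel):
            if state not in _E2F_STATES:
                problems.append(f"line {idx + 2}: unknown E2F state {state!r}")
        elif is_state(channel):
            if state not in _PATTERN_STATES:
                problems.append(f"line {idx + 2}: unknown {channel} state {state!r}")
        else:
            problems.append(f"line {idx + 2}: unknown channel {channel!r}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems[:20]))
    dup = df.duplicated(subset=["image", "nucleus", "channel"])
    if dup.any():
        raise ValueError(f"{path}: duplicate nucleus ids within an image")
    return df


def write_nucleus_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_truth(truth: SimulatedTruth, path) -> None:
    """Long-format CSV: marker, sample, time_bin (1-based), value."""
    rows = []
    for marker, y in truth.sequences.items():
        for j in range(y.shape[0]):
            for c in range(y.shape[1]):
                rows.append((marker, j, c + 1, int(y[j, c])))
    pd.DataFrame(rows, columns=["marker", "sample", "time_bin", "value"]).to_csv(
        path, index=False
    )


def read_truth(path, nb_i: int) -> SimulatedTruth:
    df = pd.read_csv(path)
    sequences = {}
    for marker, grp in df.groupby("marker"):
        wide = grp.pivot_table(index="sample", columns="time_bin", values="value")
        sequences[marker] = wide.sort_index(axis=1).to_numpy(dtype=int)
    nb_t = next(iter(sequences.values())).shape[1]
    return SimulatedTruth(nb_i, nb_t, sequences)


def write_couples(trajectories, path) -> None:
    """Long-format CSV of couples: mouse, combo, time_bin, value_m1, value_m2."""
    items = trajectories.items() if hasattr(trajectories, "items") else trajectories
    rows = []
    for (pair, mouse), couple in items:
        combo = f"{pair[0]}-{pair[1]}"
        for c in range(couple.n_bins):
            rows.append((mouse, combo, c + 1, couple.a[c], couple.b[c]))
    pd.DataFrame(
        rows, columns=["mouse", "combo", "time_bin", "value_m1", "value_m2"]
    ).to_csv(path, index=False)


def read_couples(path, nb_s: int, nb_s2: int) -> TrajectorySet:
    df = pd.read_csv(path)
    out = TrajectorySet(nb_s, nb_s2)
    for (mouse, combo), grp in df.groupby(["mouse", "combo"]):
        pair = tuple(combo.split("-"))
        grp = grp.sort_values("time_bin")
        out[pair, int(mouse)] = Couple(
            pair, int(mouse), grp["value_m1"].to_numpy(), grp["value_m2"].to_numpy()
        )
    return out


def write_shifts(shifts: dict, path) -> None:
    rows = [
        (mouse, f"{pair[0]}-{pair[1]}", int(q)) for (pair, mouse), q in shifts.items()
    ]
    pd.DataFrame(rows, columns=["mouse", "combo", "shift"]).to_csv(path, index=False)


def write_score_map(array: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def read_score_map(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float32)


def write_labels(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


@dataclass
class PipelineConfig:
    """Validated configuration of the simulation-to-MSE pipeline.

    Defaults follow the study's settings: 100 circular time bins, 4 intensity
    levels, 3 samples (2 for E2F4), Gaussian smoothing sigma 2.5 for the
    watershed step.
    """

    n_bins: int = 100
    nb_i: int = 4
    nb_s: int = 3
    nb_s2: int = 2
    noise_fraction: float = 0.0
    seed: int = 0
    cells_per_image: int = 400
    images_per_mouse: int = 3
    intensity_scale: float = 1000.0
    n_iters: int | None = None
    max_splits: int = 3
    max_forbidden: int = 4
    smoothing: float | None = None
    sigma: float = 2.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.nb_i < 1:
            raise ValueError("n_bins must be >= 2 and nb_i >= 1")
        if not 0.0 <= self.noise_fraction <= 0.5:
            raise ValueError("noise_fraction must lie in [0, 0.5]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
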