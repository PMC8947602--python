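"""Per-image intensity quantization and joint 2-D marker histograms.

Negative nuclei do not express the protein and get level 0 regardless of
their measured intensity (annotation wins over intensity: non-specific signal
can overlap the level-1 band).  Positive nuclei are binned per image into
``n_levels`` equal-width levels spanning the image's positive intensity range,
which normalizes intensity across images: level widths differ between images
because the observed minima and maxima do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import STATE_CODES, is_e2f, is_state

__all__ = ["JointHistogram", "quantize", "build_level_table", "joint_histogram"]

REQUIRED_COLUMNS = ("mouse", "image", "nucleus", "channel", "mean_intensity", "state")


def quantize(table: pd.DataFrame, channel: str, n_levels: int = 3) -> pd.Series:
    """Discrete intensity levels {0..n_levels} for one E2F channel.

    Per image: negative nuclei get 0; positives get
    ``1 + floor(n_levels * (v - v_min) / (v_max - v_min))`` clipped to
    ``n_levels``, with v_min/v_max the image's positive intensity range.  A
    degenerate image (v_max == v_min) maps all positives to ``n_levels``.
    Returns a Series indexed like the matching rows of ``table``.
    """
    if not is_e2f(channel):
        raise ValueError(f"{channel!r} is not an E2F channel")
    rows = table[table["channel"] == channel]
    levels = pd.Series(0, index=rows.index, dtype=int)
    for _, img_rows in rows.groupby("image", sort=False):
        pos = img_rows[img_rows["state"].str.lower() == "positive"]
        if pos.empty:
            continue
        v = pos["mean_intensity"].to_numpy(dtype=float)
        v_min, v_max = v.min(), v.max()
        if v_max == v_min:
            lvl = np.full(v.size, n_levels)
        else:
            lvl = 1 + np.floor(n_levels * (v - v_min) / (v_max - v_min)).astype(int)
            lvl = np.clip(lvl, 1, n_levels)
        levels.loc[pos.index] = lvl
    return levels


def build_level_table(table: pd.DataFrame, n_levels: int = 3) -> pd.DataFrame:
    """Long-format level table: E2F levels and ordinal EdU/pH3 state codes.

    Input is a per-nucleus measurement table (one row per nucleus and
    channel); output has the same keys with a ``value`` column holding the
    quantized level (E2Fs) or the ordinal state code (EdU/pH3).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {missing}")
    values = pd.Series(np.nan, index=table.index, dtype=float)
    for channel in table["channel"].unique():
        if is_e2f(channel):
            values.update(quantize(table, channel, n_levels=n_levels).astype(float))
        elif is_state(channel):
            rows = table[table["channel"] == channel]
            codes = rows["state"].str.lower().map(STATE_CODES[channel])
            if codes.isna().any():
                bad = rows.loc[codes.isna(), "state"].unique()
                raise ValueError(f"unknown {channel} states: {list(bad)}")
            values.update(codes.astype(float))
        else:
            raise ValueError(f"unknown channel {channel!r}")
    out = table[["mouse", "image", "nucleus", "channel"]].copy()
    out["value"] = values.astype(int)
    return out


@dataclass
class JointHistogram:
    """Normalized joint histogram of a marker pair over one image's nuclei."""

    pair: tuple[str, str]
    counts: np.ndarray  # raw counts h(u1, u2)
    n: int

    @property
    def H(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def _axis_size(marker: str, n_levels: int) -> int:
    return n_levels + 1 if is_e2f(marker) else 3


def joint_histogram(
    levels: pd.DataFrame,
    pair: tuple[str, str],
    image: str,
    n_levels: int = 3,
) -> JointHistogram:
    """Joint counts of nuclei over (value of pair[0], value of pair[1]).

    ``levels`` is a long-format level table; both channels must be present for
    every nucleus of the image.
    """
    m1, m2 = pair
    img = levels[levels["image"] == image]
    wide = img.pivot_table(index="nucleus", columns="channel", values="value")
    if m1 not in wide.columns or m2 not in wide.columns:
        raise ValueError(f"image {image!r} lacks channels for pair {pair}")
    wide = wide[[m1, m2]].dropna()
    n = len(wide)
    if n == 0:
        raise ValueError(f"image {image!r} has no nuclei with both channels")
    shape = (_axis_size(m1, n_levels), _axis_size(m2, n_levels))
    counts = np.zeros(shape, dtype=int)
    u1 = wide[m1].to_numpy(dtype=int)
    u2 = wide[m2].to_numpy(dtype=int)
    np.add.at(counts, (u1, u2), 1)
    return JointHistogram(pair, counts, n)
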