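"""Band handling and passive-SONAR backpropagation.

Received levels RL(f, t) at the hydrophone, in 1-min blocks over
one-third-octave (decidecade) bands spanning [f0, f1] = [141, 707] Hz, are
converted to monopole source levels band by band via the passive SONAR
equation ``SL = RL + TL`` and integrated in frequency to broadband levels
``BB = 10·log10 Σ 10^(L/10)``.  RL is dB re 1 µPa; SL/MSL is dB re 1 µPa·m
(TL is referenced to 1 m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ferrynoise.errors import MissingValueError
from ferrynoise.propagation import TransmissionLossField

logger = logging.getLogger(__name__)

__all__ = [
    "BandGrid",
    "SpectrumTimeSeries",
    "BroadbandSeries",
    "default_band_grid",
    "minute_average",
    "backpropagate",
    "broadband",
    "extract_at",
]

# ANSI nominal one-third-octave centers bracketed by the 141/707-Hz edges
_NOMINAL_CENTERS = (160.0, 200.0, 250.0, 315.0, 400.0, 500.0, 630.0)


@dataclass(frozen=True)
class BandGrid:
    """Analysis band structure on [f0, f1]."""

    band_edges: tuple[float, ...]
    band_centers: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = self.band_edges
        if len(edges) != len(self.band_centers) + 1:
            raise ValueError("need one more edge than centers")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("band edges must strictly increase")

    @property
    def f0(self) -> float:
        return self.band_edges[0]

    @property
    def f1(self) -> float:
        return self.band_edges[-1]

    @property
    def n_bands(self) -> int:
        return len(self.band_centers)

    def column_names(self) -> list[str]:
        return [f"L_{int(round(c))}Hz" for c in self.band_centers]


def default_band_grid() -> BandGrid:
    """Seven decidecade bands with base-10 edges 10^2.15 … 10^2.85 Hz.

    141 and 707 Hz are standard decidecade band edges; the bracketed nominal
    centers are 160–630 Hz.
    """
    edges = tuple(10 ** (2.15 + 0.1 * k) for k in range(8))
    return BandGrid(band_edges=edges, band_centers=_NOMINAL_CENTERS)


@dataclass
class SpectrumTimeSeries:
    """Band levels per 1-min block: RL (dB re 1 µPa) or SL (dB re 1 µPa·m)."""

    timestamps: pd.DatetimeIndex
    levels: np.ndarray  # (n_times, n_bands)
    grid: BandGrid
    reference: str = "1uPa"

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.levels.shape != (len(self.timestamps), self.grid.n_bands):
            raise ValueError("levels shape inconsistent with timestamps/grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.levels, index=self.timestamps, columns=self.grid.column_names()
        )


@dataclass
class BroadbandSeries:
    """Frequency-integrated level per block; kind is BB_RL or BB_MSL."""

    timestamps: pd.DatetimeIndex
    bb: np.ndarray
    kind: str = "BB_RL"

    def __post_init__(self) -> None:
        self.bb = np.asarray(self.bb, dtype=float)
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.bb.shape != (len(self.timestamps),):
            raise ValueError("bb shape inconsistent with timestamps")


def minute_average(
    timestamps: pd.DatetimeIndex, levels: np.ndarray, grid: BandGrid
) -> SpectrumTimeSeries:
    """Power-average sub-minute dB levels into 1-min blocks.

    Per block and band: ``10·log10(mean 10^(L/10))``.  Blocks with no samples
    are dropped (a warning is logged when input rows are non-finite).
    """
    timestamps = pd.DatetimeIndex(timestamps)
    levels = np.asarray(levels, dtype=float)
    finite = np.isfinite(levels).all(axis=1)
    if not finite.all():
        logger.warning("dropping %d sub-minute rows with non-finite levels", (~finite).sum())
    frame = pd.DataFrame(levels[finite], index=timestamps[finite].floor("min"))
    power = 10.0 ** (frame / 10.0)
    mean = power.groupby(level=0).mean()
    return SpectrumTimeSeries(
        timestamps=pd.DatetimeIndex(mean.index),
        levels=10.0 * np.log10(mean.to_numpy()),
        grid=grid,
    )


def backpropagate(
    rl: SpectrumTimeSeries, tl_field: TransmissionLossField
) -> SpectrumTimeSeries:
    """Passive SONAR equation per band: ``SL(f, t) = RL(f, t) + TL(f, d(t))``.

    Exact dB addition, no clipping.  RL blocks without a matching TL column
    (same 1-min timestamp) are skipped with a logged warning.
    """
    tl_index = pd.DatetimeIndex(tl_field.timestamps)
    pos = tl_index.get_indexer(rl.timestamps)
    keep = pos >= 0
    if not keep.all():
        logger.warning("skipping %d RL blocks without a TL column", (~keep).sum())
    return SpectrumTimeSeries(
        timestamps=rl.timestamps[keep],
        levels=rl.levels[keep] + tl_field.tl[pos[keep]],
        grid=rl.grid,
        reference="1uPa_m",
    )


def broadband(series: SpectrumTimeSeries, kind: str | None = None) -> BroadbandSeries:
    """Integrate band levels in frequency: ``BB(t) = 10·log10 Σ 10^(L/10)``."""
    if kind is None:
        kind = "BB_MSL" if series.reference == "1uPa_m" else "BB_RL"
    bb = 10.0 * np.log10(np.sum(10.0 ** (series.levels / 10.0), axis=1))
    return BroadbandSeries(timestamps=series.timestamps, bb=bb, kind=kind)


def extract_at(series: BroadbandSeries, t: pd.Timestamp) -> float:
    """Broadband value at the nearest 1-min block to ``t``.

    Ties between two equidistant blocks resolve to the earlier one; if the
    nearest block is more than one minute away a
    :class:`~ferrynoise.errors.MissingValueError` is raised.
    """
    if len(series.timestamps) == 0:
        raise MissingValueError("empty broadband series")
    t = pd.Timestamp(t)
    deltas = np.abs((series.timestamps - t).to_numpy())
    i = int(np.argmin(deltas))  # argmin takes the first (earlier) on ties
    if deltas[i] > np.timedelta64(60, "s"):
        raise MissingValueError(f"no block within 1 min of {t}")
    return float(series.bb[i])
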