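"""Shallow-water environment and transmission-loss engines.

The study site is a very shallow (h ≈ 8 m) waveguide over a slightly faster
sedimentary bottom (c_b/c_w ≈ 1.04–1.06).  Such a waveguide is a high-pass
filter: only frequencies above the modal cutoff

    f0 = c_w / (4 h sqrt(1 - (c_w/c_b)^2))

propagate to long range, which is what sets the 141-Hz lower edge of the
analysis band.  Transmission loss (TL) between the ship and the hydrophone is
provided by pluggable engines used symmetrically in the forward (scenario
synthesis) and inverse (backpropagation) directions:

* :class:`PekerisEngine` — incoherent sum over the trapped normal modes of an
  isovelocity two-layer (Pekeris) waveguide, evaluated at the receiver-side
  depth.  Levels are referenced to the 1-m value of the mode sum so that
  TL(1 m) = 0 by construction and source levels come out in dB re 1 µPa·m.
  Mode shapes satisfy the pressure-release surface, so the surface-image
  (Lloyd's mirror) interference is internal to the engine.
* :class:`SpreadingEngine` — practical spreading law
  ``k·log10(r) + α·r/1000`` as a degraded-configuration fallback.

Below the cutoff no trapped mode exists; the Pekeris engine then returns the
practical-spreading loss plus a documented evanescent penalty (default 10 dB
per 100 m beyond 100 m).  The analysis band [f0, f1] never enters this regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from ferrynoise.errors import (
    InvalidEnvironmentError,
    InvalidRangeError,
    NoCutoffError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnvironmentModel",
    "TransmissionLossField",
    "PekerisEngine",
    "SpreadingEngine",
    "cutoff_frequency",
    "pekeris_modes",
    "pekeris_tl",
    "practical_spreading_tl",
    "tl_along_track",
]


@dataclass(frozen=True)
class EnvironmentModel:
    """Two-layer shallow-water environment at the hydrophone site.

    Parameters
    ----------
    water_sound_speed
        Homogeneous water sound speed c_w, m/s.
    seabed_sound_speed
        Homogeneous seabed sound speed c_b, m/s.  The harbor's clay/silt/sand
        mixture gives c_b/c_w ≈ 1.04–1.06; the default ratio 1.06 with h = 8 m
        reproduces the 141-Hz cutoff.
    water_column_height
        Water column height h at the hydrophone, m.
    water_density, sediment_density
        kg/m³.
    sediment_attenuation
        Compressional attenuation in the bottom, dB per wavelength (0 =
        lossless half-space, the default).
    hydrophone_height_above_seabed
        m; the instrument was moored 2 m above the seabed.
    source_depth
        Acoustic-center depth of the ship below the surface, m.
    bathymetry_profile
        Optional ordered ``(range_m, depth_m)`` pairs on a 100-m grid along
        the route; used for range sampling/diagnostics (the mode solution uses
        the receiver-side depth).
    evanescent_penalty_db_per_100m
        Extra loss applied below cutoff beyond 100 m.
    """

    water_sound_speed: float = 1500.0
    seabed_sound_speed: float = 1590.0
    water_column_height: float = 8.0
    water_density: float = 1000.0
    sediment_density: float = 1700.0
    sediment_attenuation: float = 0.0
    hydrophone_height_above_seabed: float = 2.0
    source_depth: float = 3.0
    bathymetry_profile: tuple[tuple[float, float], ...] = ()
    evanescent_penalty_db_per_100m: float = 10.0

    def __post_init__(self) -> None:
        if self.water_sound_speed <= 0:
            raise InvalidEnvironmentError("water sound speed must be positive")
        if self.water_column_height <= 0:
            raise InvalidEnvironmentError("water column height must be positive")
        if not (0 < self.hydrophone_height_above_seabed < self.water_column_height):
            raise InvalidEnvironmentError(
                "hydrophone height must sit inside the water column"
            )
        if not (0 < self.source_depth < self.water_column_height):
            raise InvalidEnvironmentError("source depth must sit inside the water column")
        if self.bathymetry_profile:
            ranges = [r for r, _ in self.bathymetry_profile]
            depths = [d for _, d in self.bathymetry_profile]
            if any(b <= a for a, b in zip(ranges, ranges[1:])):
                raise InvalidEnvironmentError("bathymetry ranges must strictly increase")
            if any(d <= 0 for d in depths):
                raise InvalidEnvironmentError("bathymetry depths must be positive")

    @property
    def receiver_depth(self) -> float:
        """Hydrophone depth below the surface, m."""
        return self.water_column_height - self.hydrophone_height_above_seabed

    def depth_at_range(self, range_m: float) -> float:
        """Nearest-node bathymetry depth, or the receiver-side depth if no profile."""
        if not self.bathymetry_profile:
            return self.water_column_height
        ranges = np.array([r for r, _ in self.bathymetry_profile])
        depths = np.array([d for _, d in self.bathymetry_profile])
        return float(depths[np.argmin(np.abs(ranges - range_m))])


@dataclass
class TransmissionLossField:
    """TL per (time, band) along a track, dB relative to the 1-m reference."""

    timestamps: np.ndarray
    band_frequencies: np.ndarray
    ranges: np.ndarray
    tl: np.ndarray  # shape (n_times, n_bands)

    def __post_init__(self) -> None:
        self.tl = np.asarray(self.tl, dtype=float)
        if self.tl.shape != (len(self.timestamps), len(self.band_frequencies)):
            raise ValueError("tl shape inconsistent with timestamps/bands")


def cutoff_frequency(env: EnvironmentModel) -> float:
    """Lowest propagating frequency of the waveguide, Hz.

    ``f0 = c_w / (4 h sqrt(1 - (c_w/c_b)^2))`` — the quarter-wavelength
    condition for the first trapped mode of a pressure-release /
    penetrable-bottom waveguide.

    Raises
    ------
    NoCutoffError
        If the seabed is not faster than the water (no modal cutoff exists).
    InvalidEnvironmentError
        If the water column height is non-positive.
    """
    if env.water_column_height <= 0:
        raise InvalidEnvironmentError("water column height must be positive")
    cw, cb = env.water_sound_speed, env.seabed_sound_speed
    if cb <= cw:
        raise NoCutoffError("seabed sound speed must exceed water sound speed")
    return cw / (4.0 * env.water_column_height * math.sqrt(1.0 - (cw / cb) ** 2))


# dB/wavelength -> imaginary loss tangent: alpha_lambda = 40*pi*log10(e)*delta
_DB_PER_LAMBDA_TO_TANGENT = 1.0 / (40.0 * math.pi * math.log10(math.e))


def pekeris_modes(
    env: EnvironmentModel, frequency: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Trapped normal modes of the Pekeris waveguide at ``frequency``.

    Returns ``(gamma, k_r, norm, alpha)`` — vertical wavenumbers in water,
    horizontal wavenumbers, mode normalization integrals (with 1/ρ weight),
    and modal attenuation coefficients (nepers/m) from first-order
    perturbation of the bottom loss tangent.  Empty arrays below cutoff.

    The characteristic equation for mode shapes ``sin(γ z)`` (z from the
    pressure-release surface) over an evanescent bottom tail is

        ρ_b γ cos(γ h) + ρ_w β sin(γ h) = 0,   β = sqrt(γ_max² − γ²),

    with one root per interval ``((n−1/2)π/h, min(nπ/h, γ_max))``.
    """
    h = env.water_column_height
    rho_w, rho_b = env.water_density, env.sediment_density
    k_w = 2.0 * math.pi * frequency / env.water_sound_speed
    k_b = 2.0 * math.pi * frequency / env.seabed_sound_speed
    gamma_max_sq = k_w**2 - k_b**2
    if gamma_max_sq <= 0:
        return (np.array([]),) * 4
    gamma_max = math.sqrt(gamma_max_sq)

    def char(g: float) -> float:
        beta = math.sqrt(max(gamma_max_sq - g * g, 0.0))
        return rho_b * g * math.cos(g * h) + rho_w * beta * math.sin(g * h)

    gammas = []
    n = 1
    while (n - 0.5) * math.pi / h < gamma_max:
        lo = (n - 0.5) * math.pi / h * (1.0 + 1e-12)
        hi = min(n * math.pi / h, gamma_max) * (1.0 - 1e-12)
        if hi > lo and char(lo) * char(hi) < 0:
            gammas.append(brentq(char, lo, hi, xtol=1e-14, rtol=1e-15))
        n += 1
    if not gammas:
        return (np.array([]),) * 4

    gamma = np.array(gammas)
    beta = np.sqrt(np.maximum(gamma_max_sq - gamma**2, 1e-30))
    k_r = np.sqrt(k_w**2 - gamma**2)
    # ∫ψ²/ρ dz with ψ = sin(γz) in water and sin(γh)·exp(−β(z−h)) below
    norm = (h / 2.0 - np.sin(2.0 * gamma * h) / (4.0 * gamma)) / rho_w + np.sin(
        gamma * h
    ) ** 2 / (2.0 * beta * rho_b)
    if env.sediment_attenuation > 0:
        delta = env.sediment_attenuation * _DB_PER_LAMBDA_TO_TANGENT
        im_kb_sq = 2.0 * k_b**2 * delta
        bottom_integral = np.sin(gamma * h) ** 2 / (2.0 * beta * rho_b)
        alpha = im_kb_sq * bottom_integral / (2.0 * k_r * norm)
    else:
        alpha = np.zeros_like(gamma)
    return gamma, k_r, norm, alpha


def _mode_sum_intensity(
    env: EnvironmentModel, frequency: float, ranges: np.ndarray, coherent: bool
) -> np.ndarray:
    gamma, k_r, norm, alpha = pekeris_modes(env, frequency)
    if gamma.size == 0:
        raise NoCutoffError(f"no trapped mode at {frequency} Hz")
    amp = (
        np.sin(gamma * env.source_depth)
        * np.sin(gamma * env.receiver_depth)
        / norm
    )
    r = ranges[:, None]
    if coherent:
        p = np.sum(
            amp
            * np.exp(1j * k_r * r - alpha * r)
            / np.sqrt(k_r * r),
            axis=1,
        )
        return np.abs(p) ** 2
    return np.sum(amp**2 * np.exp(-2.0 * alpha * r) / (k_r * r), axis=1)


def pekeris_tl(
    env: EnvironmentModel,
    frequency: float,
    range_m: float | np.ndarray,
    coherent: bool = False,
) -> float | np.ndarray:
    """Transmission loss of the Pekeris waveguide, dB re the 1-m level.

    Incoherent (band/time-averaged) trapped-mode sum by default; a coherent
    sum is available behind ``coherent=True``.  Deterministic and exactly 0 at
    the 1-m reference range.  Below the modal cutoff the engine falls back to
    practical spreading (15 log r) plus the documented evanescent penalty.
    """
    scalar = np.isscalar(range_m)
    r = np.atleast_1d(np.asarray(range_m, dtype=float))
    if np.any(r < 1.0):
        raise InvalidRangeError("ranges below the 1-m reference are not defined")
    if frequency <= 0:
        raise InvalidEnvironmentError("frequency must be positive")

    try:
        f0 = cutoff_frequency(env)
    except NoCutoffError:
        f0 = 0.0
    if f0 and frequency <= f0:
        penalty = env.evanescent_penalty_db_per_100m * np.maximum(r - 100.0, 0.0) / 100.0
        tl = practical_spreading_tl(frequency, r, 15.0, 0.0) + penalty
        return float(tl[0]) if scalar else tl

    intensity = _mode_sum_intensity(env, frequency, r, coherent)
    ref = _mode_sum_intensity(env, frequency, np.array([1.0]), coherent)[0]
    tl = -10.0 * np.log10(intensity / ref)
    return float(tl[0]) if scalar else tl


def practical_spreading_tl(
    frequency: float,
    range_m: float | np.ndarray,
    geometry_coefficient: float = 15.0,
    absorption_db_per_km: float = 0.0,
) -> float | np.ndarray:
    """Practical spreading loss ``k·log10(r) + α·r/1000`` in dB.

    ``frequency`` is accepted for engine-interface symmetry; the law itself is
    frequency-independent unless an absorption rate is supplied.
    """
    if not 10.0 <= geometry_coefficient <= 20.0:
        raise InvalidEnvironmentError("geometry coefficient must be in [10, 20]")
    scalar = np.isscalar(range_m)
    r = np.atleast_1d(np.asarray(range_m, dtype=float))
    if np.any(r < 1.0):
        raise InvalidRangeError("ranges below the 1-m reference are not defined")
    tl = geometry_coefficient * np.log10(r) + absorption_db_per_km * r / 1000.0
    return float(tl[0]) if scalar else tl


class PekerisEngine:
    """TL engine wrapping :func:`pekeris_tl` for a fixed environment."""

    name = "pekeris"

    def __init__(self, env: EnvironmentModel, coherent: bool = False) -> None:
        self.env = env
        self.coherent = coherent

    def tl(self, frequency: float, range_m: float | np.ndarray) -> np.ndarray:
        return pekeris_tl(self.env, frequency, range_m, coherent=self.coherent)


class SpreadingEngine:
    """Practical-spreading fallback engine."""

    name = "spreading"

    def __init__(
        self, geometry_coefficient: float = 15.0, absorption_db_per_km: float = 0.0
    ) -> None:
        self.geometry_coefficient = geometry_coefficient
        self.absorption_db_per_km = absorption_db_per_km

    def tl(self, frequency: float, range_m: float | np.ndarray) -> np.ndarray:
        return practical_spreading_tl(
            frequency, range_m, self.geometry_coefficient, self.absorption_db_per_km
        )


def tl_along_track(
    env: EnvironmentModel,
    band_frequencies: Sequence[float],
    timestamps: Sequence,
    distances_m: Sequence[float],
    engine=None,
) -> TransmissionLossField:
    """Evaluate the selected engine per track sample and band.

    Samples with missing (NaN) distances are skipped with a logged warning;
    an empty track yields an empty field.  When a bathymetry profile is
    present the nearest 100-m node depth is sampled for diagnostics.
    """
    if engine is None:
        engine = PekerisEngine(env)
    timestamps = np.asarray(timestamps)
    distances = np.asarray(distances_m, dtype=float)
    freqs = np.asarray(band_frequencies, dtype=float)
    keep = np.isfinite(distances)
    if not keep.all():
        logger.warning("skipping %d track samples with missing distance", (~keep).sum())
    timestamps, distances = timestamps[keep], distances[keep]
    if distances.size == 0:
        return TransmissionLossField(timestamps, freqs, distances, np.empty((0, len(freqs))))
    tl = np.column_stack([engine.tl(f, distances) for f in freqs])
    if env.bathymetry_profile:
        # range sampling on the 100-m bathymetry grid, diagnostic only
        _ = [env.depth_at_range(d) for d in distances[:: max(1, len(distances) // 8)]]
    return TransmissionLossField(timestamps, freqs, distances, tl)
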