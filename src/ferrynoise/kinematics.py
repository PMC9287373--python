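"""AIS kinematics: distance, speed-through-water, derivatives, and events.

AIS records (timestamp, lat/lon, SOG, COG) joined with the nearest-in-time
surface-current sample give per-minute kinematics relative to the hydrophone:
distance d, speed-through-water STW = |v_ground − v_current|, acceleration
(knots·min⁻¹) and jerk (knots·min⁻²).  Two events define the operating
modes: the closest point of approach (CPA, minimum d) and the speed-change
event t_acc — the jerk-sign-change instant between the two peaks of the
characteristic double-peak acceleration signature seen at launching and
docking.

Bearing convention: COG and current orientation are "toward" directions in
degrees clockwise from true north.  STW/acceleration series are smoothed with
a centered 3-min boxcar before differentiation (1-min AIS grid).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ferrynoise.errors import (
    InsufficientDataError,
    InvalidCoordinateError,
    NoCPAError,
    SinglePeakError,
    StationaryTrackError,
    UnusableTransitError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_M",
    "PhaseEvents",
    "distance_to_hydrophone",
    "speed_through_water",
    "boxcar_smooth",
    "kinematic_derivatives",
    "find_cpa",
    "detect_speed_change_event",
    "phase_windows",
    "classify_direction",
    "to_minute_grid",
    "build_track",
]

EARTH_RADIUS_M = 6_371_008.8  # WGS84 mean radius
KNOT_MS = 1852.0 / 3600.0

#: smoothed-STW threshold separating rest from way-on (knots)
MOTION_THRESHOLD_KN = 1.0
#: double-peak detection floor (knots/min) and minimum peak separation (min)
PEAK_PROMINENCE = 0.3
PEAK_SEPARATION_MIN = 2
#: AIS gaps longer than this flag the transit unusable (min)
MAX_GAP_MIN = 5.0


@dataclass
class PhaseEvents:
    """CPA and speed-change event measurements plus the phase windows."""

    t_cpa: pd.Timestamp
    d_cpa: float
    stw_cpa: float
    a_cpa: float
    t_acc: pd.Timestamp
    d_acc: float
    stw_acc: float
    a_acc: float
    window_accel: tuple[pd.Timestamp, pd.Timestamp]
    window_design_speed: tuple[pd.Timestamp, pd.Timestamp]
    window_decel: tuple[pd.Timestamp, pd.Timestamp]
    peaks: tuple[pd.Timestamp, pd.Timestamp] | None = None


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise InvalidCoordinateError("latitude/longitude out of range")


def distance_to_hydrophone(lat, lon, site_lat: float, site_lon: float):
    """Great-circle (haversine) distance in meters, WGS84 mean radius."""
    _check_coords(lat, lon)
    _check_coords(site_lat, site_lon)
    phi1, phi2 = np.radians(lat), math.radians(site_lat)
    dphi = np.radians(np.asarray(site_lat) - np.asarray(lat))
    dlam = np.radians(np.asarray(site_lon) - np.asarray(lon))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
    return float(d) if np.isscalar(lat) else d


def speed_through_water(sog, cog, current_orientation, current_speed):
    """STW = |v_ground − v_current| in knots.

    Both vectors point toward the direction of travel/flow, bearings in
    degrees true.
    """
    sog = np.asarray(sog, dtype=float)
    cog_r = np.radians(np.asarray(cog, dtype=float))
    ori_r = np.radians(np.asarray(current_orientation, dtype=float))
    cs = np.asarray(current_speed, dtype=float)
    de = sog * np.sin(cog_r) - cs * np.sin(ori_r)
    dn = sog * np.cos(cog_r) - cs * np.cos(ori_r)
    stw = np.hypot(de, dn)
    return float(stw) if stw.ndim == 0 else stw


def boxcar_smooth(values, width: int = 3) -> np.ndarray:
    """Centered moving average with edge renormalization.

    ``width`` must be odd; the window is truncated (and renormalized) at the
    series edges, so a constant series is returned unchanged.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("boxcar width must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    return (
        pd.Series(values)
        .rolling(window=width, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def kinematic_derivatives(stw, dt_min: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Acceleration (kn/min) and jerk (kn/min²) of a regularly spaced series.

    Central differences on interior samples, one-sided at the two boundary
    samples (callers should treat those as flagged).
    """
    stw = np.asarray(stw, dtype=float)
    if stw.size < 3:
        raise InsufficientDataError("need at least 3 samples for derivatives")
    accel = np.gradient(stw, dt_min)
    jerk = np.gradient(accel, dt_min)
    return accel, jerk


def find_cpa(track: pd.DataFrame) -> tuple[pd.Timestamp, float, float, float]:
    """Sample minimizing distance; earliest timestamp on ties.

    ``track`` needs columns ``d_m, stw_kn, a_kn_per_min`` on a DatetimeIndex.
    """
    d = track["d_m"].to_numpy(dtype=float)
    if len(d) == 0 or not np.isfinite(d).any():
        raise NoCPAError("no usable distance samples")
    i = int(np.nanargmin(d))  # first index on ties
    row = track.iloc[i]
    return track.index[i], float(row["d_m"]), float(row["stw_kn"]), float(row["a_kn_per_min"])


def detect_speed_change_event(
    times: pd.DatetimeIndex,
    accel: np.ndarray,
    phase: str = "acceleration",
    prominence: float = PEAK_PROMINENCE,
    separation_min: float = PEAK_SEPARATION_MIN,
) -> tuple[pd.Timestamp, tuple[pd.Timestamp, pd.Timestamp]]:
    """Locate t_acc inside a speed-change window.

    The two highest-prominence peaks of the (smoothed) acceleration — of
    −acceleration for a deceleration phase — form the double-peak signature;
    t_acc is the jerk-sign-change instant between them, i.e. the trough of the
    signal between the peaks.  Raises
    :class:`~ferrynoise.errors.SinglePeakError` when fewer than two peaks meet
    the prominence floor.
    """
    signal = np.asarray(accel, dtype=float)
    if phase == "deceleration":
        signal = -signal
    if len(times) >= 2:
        dt_min = (times[1] - times[0]).total_seconds() / 60.0
    else:
        dt_min = 1.0
    distance = max(1, int(round(separation_min / dt_min)))
    peaks, props = find_peaks(signal, prominence=prominence, distance=distance)
    if len(peaks) < 2:
        raise SinglePeakError("double-peak signature not found")
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    p1, p2 = int(top2.min()), int(top2.max())
    trough = p1 + 1 + int(np.argmin(signal[p1 + 1 : p2]))
    return times[trough], (times[p1], times[p2])


def classify_direction(track: pd.DataFrame, dock_lat: float, dock_lon: float) -> str:
    """Outgoing if the track moves away from the departure dock, else incoming."""
    d0 = distance_to_hydrophone(
        float(track["lat"].iloc[0]), float(track["lon"].iloc[0]), dock_lat, dock_lon
    )
    d1 = distance_to_hydrophone(
        float(track["lat"].iloc[-1]), float(track["lon"].iloc[-1]), dock_lat, dock_lon
    )
    return "outgoing" if d1 > d0 else "incoming"


def to_minute_grid(ais: pd.DataFrame) -> pd.DataFrame:
    """Bucket AIS records to a regular 1-min grid by nearest timestamp.

    Duplicate records within a minute are averaged (circular mean for COG).
    """
    frame = ais.copy()
    frame["minute"] = pd.DatetimeIndex(frame["timestamp"]).round("min")
    cog_r = np.radians(frame["cog_deg"].to_numpy(dtype=float))
    frame["_ce"] = np.cos(cog_r)
    frame["_se"] = np.sin(cog_r)
    grouped = frame.groupby("minute").agg(
        lat=("lat", "mean"),
        lon=("lon", "mean"),
        sog_kn=("sog_kn", "mean"),
        _ce=("_ce", "mean"),
        _se=("_se", "mean"),
    )
    cog = np.degrees(np.arctan2(grouped["_se"], grouped["_ce"])) % 360.0
    grouped["cog_deg"] = np.where(cog >= 360.0, 0.0, cog)  # fold the -0° wraparound
    return grouped.drop(columns=["_ce", "_se"])


def build_track(
    ais: pd.DataFrame,
    currents: pd.DataFrame,
    site_lat: float,
    site_lon: float,
    smooth_width: int = 3,
) -> pd.DataFrame:
    """Per-minute kinematics table from AIS records and a current series.

    Returns a DataFrame indexed by minute with columns ``d_m, stw_kn,
    a_kn_per_min, jerk, boundary_flag``.  The nearest-in-time current sample
    is joined to each AIS minute; STW is smoothed with the 3-min boxcar before
    differentiation.
    """
    grid = to_minute_grid(ais)
    if len(grid) < 3:
        raise InsufficientDataError("need at least 3 AIS minutes")
    cur = currents.sort_values("timestamp")
    joined = pd.merge_asof(
        grid.reset_index().rename(columns={"minute": "timestamp"}),
        cur,
        on="timestamp",
        direction="nearest",
        suffixes=("", "_cur"),
    ).set_index("timestamp")
    stw_raw = speed_through_water(
        joined["sog_kn"], joined["cog_deg"], joined["orientation_deg"], joined["speed_kn"]
    )
    stw = boxcar_smooth(stw_raw, smooth_width)
    accel, jerk = kinematic_derivatives(stw)
    d = distance_to_hydrophone(
        joined["lat"].to_numpy(), joined["lon"].to_numpy(), site_lat, site_lon
    )
    out = pd.DataFrame(
        {
            "lat": joined["lat"],
            "lon": joined["lon"],
            "d_m": d,
            "stw_kn": stw,
            "a_kn_per_min": accel,
            "jerk": jerk,
            "boundary_flag": False,
        },
        index=joined.index,
    )
    out.iloc[0, out.columns.get_loc("boundary_flag")] = True
    out.iloc[-1, out.columns.get_loc("boundary_flag")] = True
    return out


def phase_windows(
    track: pd.DataFrame,
    direction: str,
    motion_threshold: float = MOTION_THRESHOLD_KN,
    max_gap_min: float = MAX_GAP_MIN,
) -> PhaseEvents:
    """Detect CPA, the speed-change event, and the three phase windows.

    Acceleration kickoff is the first minute the smoothed STW rises through
    the motion threshold; deceleration end is the last minute above it.  The
    window of interest is [kickoff, t_CPA] for outgoing transits and
    [t_CPA, decel end] for incoming ones; the double-peak search runs inside
    that window.  Mid-transit AIS gaps longer than ``max_gap_min`` flag the
    transit unusable.
    """
    stw = track["stw_kn"].to_numpy(dtype=float)
    moving = stw >= motion_threshold
    if not moving.any():
        raise StationaryTrackError("smoothed STW never exceeds the motion threshold")
    idx = track.index
    kickoff = idx[int(np.argmax(moving))]
    decel_end = idx[len(moving) - 1 - int(np.argmax(moving[::-1]))]

    span = track.loc[kickoff:decel_end]
    gaps = span.index.to_series().diff().dt.total_seconds().dropna() / 60.0
    if (gaps > max_gap_min).any():
        raise UnusableTransitError(
            f"AIS gap of {gaps.max():.1f} min inside the transit"
        )

    t_cpa, d_cpa, stw_cpa, a_cpa = find_cpa(track)

    # peak search includes the rest tail beyond the kickoff/decel-end bounds:
    # the boundary samples sit on a pulse flank and would clip its prominence
    if direction == "outgoing":
        window = track.loc[:t_cpa]
        phase = "acceleration"
    elif direction == "incoming":
        window = track.loc[t_cpa:]
        phase = "deceleration"
    else:
        raise ValueError(f"unknown direction {direction!r}")

    t_acc, peaks = detect_speed_change_event(
        window.index, window["a_kn_per_min"].to_numpy(), phase=phase
    )
    row = track.loc[t_acc]

    # plateau bounds: first/last minute at >=95% of the near-operational speed
    plateau = np.quantile(stw[moving], 0.9)
    at_speed = stw >= 0.95 * plateau
    first_at = idx[int(np.argmax(at_speed))]
    last_at = idx[len(at_speed) - 1 - int(np.argmax(at_speed[::-1]))]

    return PhaseEvents(
        t_cpa=t_cpa,
        d_cpa=d_cpa,
        stw_cpa=stw_cpa,
        a_cpa=a_cpa,
        t_acc=t_acc,
        d_acc=float(row["d_m"]),
        stw_acc=float(row["stw_kn"]),
        a_acc=float(row["a_kn_per_min"]),
        window_accel=(kickoff, first_at),
        window_design_speed=(first_at, last_at),
        window_decel=(last_at, decel_end),
        peaks=peaks,
    )
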