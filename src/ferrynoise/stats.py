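"""Per-transit summaries and the comparative statistics.

One row per transit (the study's per-transit table analog): kinematics and
broadband MSL extracted at t_CPA and at the speed-change event t_acc, plus a
scheduled time-of-day slot.  On top of those rows: per-(mode × direction)
means ± 1σ, the ΔBB ≡ BB_acc − BB_CPA distributions with maximum-likelihood
normal fits, the two-sample Kolmogorov–Smirnov statistic D between the two
operating modes, and a Gaussian linear mixed model

    BB ~ intercept + d + STW + a + (1 | time-of-day slot)

fitted by REML with Wald 95% confidence intervals and p-values.  Distance
enters the model in kilometres.  dB values are averaged arithmetically,
matching how "mean ± 1σ dB" is conventionally reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from ferrynoise.errors import InsufficientDataError, UnusableTransitError
from ferrynoise.kinematics import PhaseEvents
from ferrynoise.spectral import BroadbandSeries, extract_at
from ferrynoise.errors import MissingValueError

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEDULE_SLOTS",
    "DeltaBBResult",
    "KSResult",
    "MixedModelResult",
    "assign_slot",
    "summarize_transit",
    "percent_time_in_speed_change",
    "delta_bb",
    "ks_two_sample",
    "fit_mixed_model",
    "mode_means",
]

#: scheduled six-trips-a-day grid: three departures, three arrivals (EDT)
SCHEDULE_SLOTS = {
    "outgoing": ("08:00", "12:00", "16:00"),
    "incoming": ("11:00", "15:00", "19:00"),
}


@dataclass
class DeltaBBResult:
    direction: str
    deltas: np.ndarray
    fitted_mean: float
    fitted_sigma: float


@dataclass
class KSResult:
    D: float
    n1: int
    n2: int


@dataclass
class MixedModelResult:
    mode: str
    direction: str
    fixed_effects: pd.DataFrame  # index: term; cols: estimate, ci_low, ci_high, p_wald
    random_intercept_variance: float
    residual_variance: float
    n_obs: int
    singular: bool = False


def assign_slot(t: pd.Timestamp, direction: str) -> str:
    """Nearest scheduled slot for a departure (outgoing) or arrival (incoming)."""
    t = pd.Timestamp(t)
    minutes = t.hour * 60 + t.minute
    best = min(
        SCHEDULE_SLOTS[direction],
        key=lambda s: abs(minutes - (int(s[:2]) * 60 + int(s[3:]))),
    )
    return f"{best} {direction}"


def summarize_transit(
    events: PhaseEvents,
    bb_msl: BroadbandSeries,
    transit_id: str,
    direction: str,
    strict: bool = True,
) -> dict:
    """Extract the per-transit summary row at t_CPA and t_acc.

    With ``strict=True`` (default) a missing broadband extraction at either
    event excludes the transit.  The pipeline's partial mode
    (``strict=False``) instead records NaN for the missing half so a transit
    can still contribute its other operating mode — emulating a study day
    where only one measurement was usable.
    """
    try:
        bb_cpa = extract_at(bb_msl, events.t_cpa)
    except MissingValueError:
        if strict:
            raise UnusableTransitError(f"{transit_id}: no BB block at t_CPA")
        logger.info("%s: no BB block at t_CPA; keeping acc half only", transit_id)
        bb_cpa = np.nan
    try:
        bb_acc = extract_at(bb_msl, events.t_acc)
    except MissingValueError:
        if strict:
            raise UnusableTransitError(f"{transit_id}: no BB block at t_acc")
        logger.info("%s: no BB block at t_acc; keeping CPA half only", transit_id)
        bb_acc = np.nan
    slot_time = events.window_accel[0] if direction == "outgoing" else events.window_decel[1]
    return {
        "transit_id": transit_id,
        "date": pd.Timestamp(events.t_cpa).date().isoformat(),
        "direction": direction,
        "t_cpa": events.t_cpa,
        "d_cpa_m": events.d_cpa,
        "stw_cpa_kn": events.stw_cpa,
        "a_cpa_kn_per_min": events.a_cpa,
        "bb_cpa_db": bb_cpa,
        "t_acc": events.t_acc,
        "d_acc_m": events.d_acc,
        "stw_acc_kn": events.stw_acc,
        "a_acc_kn_per_min": events.a_acc,
        "bb_acc_db": bb_acc,
        "time_of_day_slot": assign_slot(slot_time, direction),
    }


def percent_time_in_speed_change(duration_min: float, accel_min: float, decel_min: float) -> float:
    """Share of transit time in acceleration or deceleration, percent.

    ``100·(accel+decel)/duration`` rounded half-up to one decimal.
    """
    if duration_min == 0:
        raise InsufficientDataError("zero transit duration")
    if accel_min < 0 or decel_min < 0 or accel_min + decel_min > duration_min:
        raise ValueError("phase durations must be non-negative and fit the transit")
    pct = Decimal(100) * (Decimal(str(accel_min)) + Decimal(str(decel_min))) / Decimal(str(duration_min))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def delta_bb(summaries: pd.DataFrame, direction: str) -> DeltaBBResult:
    """Per-transit ΔBB = BB_acc − BB_CPA with a maximum-likelihood normal fit.

    The fit is the sample mean and the population (1/n) standard deviation;
    only transits with both modes measured contribute.
    """
    rows = summaries[summaries["direction"] == direction]
    deltas = (rows["bb_acc_db"] - rows["bb_cpa_db"]).dropna().to_numpy(dtype=float)
    if deltas.size < 2:
        raise InsufficientDataError(f"need >= 2 paired {direction} transits")
    mu, sigma = sps.norm.fit(deltas)
    return DeltaBBResult(direction=direction, deltas=deltas, fitted_mean=float(mu), fitted_sigma=float(sigma))


def ks_two_sample(x, y) -> KSResult:
    """Two-sample Kolmogorov–Smirnov statistic D = sup |ECDF_x − ECDF_y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    d = sps.ks_2samp(x, y, method="asymp").statistic
    return KSResult(D=float(d), n1=x.size, n2=y.size)


def fit_mixed_model(
    summaries: pd.DataFrame,
    mode: str,
    direction: str,
    distance_unit_m: float = 1000.0,
) -> MixedModelResult:
    """Gaussian linear mixed model BB ~ d + STW + a + (1 | slot), REML.

    ``mode`` selects the predictor/response set: ``"cpa"`` uses the CPA
    measurements, ``"acc"`` the speed-change ones.  Distance is expressed in
    km by default.  Wald 95% CIs and p-values per fixed effect.  A singular
    fit (vanishing random-intercept variance) is returned with
    ``singular=True`` rather than raising.
    """
    if mode not in {"cpa", "acc"}:
        raise ValueError("mode must be 'cpa' or 'acc'")
    rows = summaries[summaries["direction"] == direction].dropna(
        subset=[f"bb_{mode}_db", f"d_{mode}_m", f"stw_{mode}_kn", f"a_{mode}_kn_per_min"]
    )
    if len(rows) < 10:
        raise InsufficientDataError("need >= 10 transits for the mixed model")
    from statsmodels.regression.mixed_linear_model import MixedLM

    endog = rows[f"bb_{mode}_db"].to_numpy(dtype=float)
    exog = pd.DataFrame(
        {
            "Intercept": 1.0,
            "d": rows[f"d_{mode}_m"].to_numpy(dtype=float) / distance_unit_m,
            "STW": rows[f"stw_{mode}_kn"].to_numpy(dtype=float),
            "a": rows[f"a_{mode}_kn_per_min"].to_numpy(dtype=float),
        }
    )
    groups = rows["time_of_day_slot"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = MixedLM(endog, exog, groups=groups).fit(reml=True)
        est = fit.fe_params
        se = fit.bse_fe
    z = sps.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "estimate": est,
            "ci_low": est - z * se,
            "ci_high": est + z * se,
            "p_wald": 2.0 * sps.norm.sf(np.abs(est / se)),
        }
    )
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    return MixedModelResult(
        mode=mode,
        direction=direction,
        fixed_effects=table,
        random_intercept_variance=re_var,
        residual_variance=float(fit.scale),
        n_obs=len(rows),
        singular=bool(re_var < 1e-8),
    )


def mode_means(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean ± 1σ (sample SD) of broadband MSL per (mode × direction) cell.

    Cells with fewer than two measured transits are omitted with a warning.
    dB values are averaged arithmetically.
    """
    records = []
    for mode, col in (("cpa", "bb_cpa_db"), ("acc", "bb_acc_db")):
        for direction, rows in summaries.groupby("direction"):
            vals = rows[col].dropna().to_numpy(dtype=float)
            if vals.size < 2:
                logger.warning("omitting %s/%s cell with n=%d", mode, direction, vals.size)
                continue
            records.append(
                {
                    "mode": mode,
                    "direction": direction,
                    "mean_db": float(np.mean(vals)),
                    "sd_db": float(np.std(vals, ddof=1)),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame.from_records(records)
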