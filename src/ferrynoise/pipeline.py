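"""Run orchestration: scenario → kinematics → backpropagation → statistics.

The analysis path mirrors the study's production chain: per transit, build
the 1-min kinematics track, detect the CPA and speed-change events, evaluate
transmission loss along the line of sight, backpropagate the received band
spectra to source levels, integrate to broadband, and extract the two
operating-mode measurements; then assemble the per-transit table and the
comparative statistics (per-mode means, ΔBB fits, KS separation, mixed
models).  Unusable transits are excluded with logged reason codes, never
silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ferrynoise.errors import FerryNoiseError, InsufficientDataError
from ferrynoise.kinematics import build_track, classify_direction, phase_windows
from ferrynoise.propagation import (
    EnvironmentModel,
    PekerisEngine,
    SpreadingEngine,
    tl_along_track,
)
from ferrynoise.scenarios import Scenario, _enu_to_latlon
from ferrynoise.spectral import (
    BandGrid,
    SpectrumTimeSeries,
    backpropagate,
    broadband,
    default_band_grid,
)
from ferrynoise.stats import delta_bb, fit_mixed_model, ks_two_sample, mode_means, summarize_transit

logger = logging.getLogger(__name__)

__all__ = ["AnalysisResult", "analyze_scenario", "load_scenario_dir", "run_analysis"]


@dataclass
class AnalysisResult:
    summaries: pd.DataFrame
    sl_series: dict  # transit_id -> SpectrumTimeSeries (backpropagated SL)
    bb_series: dict  # transit_id -> (BB_RL, BB_MSL)
    exclusions: list  # (transit_id, reason)
    report: dict


def _engine_from_config(env: EnvironmentModel, engine: str, coeff: float, absorption: float):
    if engine == "pekeris":
        return PekerisEngine(env)
    if engine == "spreading":
        return SpreadingEngine(coeff, absorption)
    raise FerryNoiseError(f"unknown engine {engine!r}")


def analyze_scenario(
    ais: pd.DataFrame,
    currents: pd.DataFrame,
    rl: pd.DataFrame,
    env: EnvironmentModel,
    site_lat: float,
    site_lon: float,
    dock_lat: float,
    dock_lon: float,
    grid: BandGrid | None = None,
    engine=None,
    strict: bool = False,
) -> AnalysisResult:
    """Full analysis of a scenario held in memory.

    ``ais`` needs a ``transit_id`` column; ``rl`` is indexed by block
    timestamp with one column per band.  With ``strict=False`` a transit
    missing one broadband extraction keeps its other operating mode.
    """
    grid = grid or default_band_grid()
    engine = engine or PekerisEngine(env)
    rows, exclusions = [], []
    sl_series, bb_series = {}, {}
    for transit_id, records in ais.groupby("transit_id", sort=True):
        try:
            track = build_track(records, currents, site_lat, site_lon)
            direction = classify_direction(track, dock_lat, dock_lon)
            events = phase_windows(track, direction)
            window = rl.loc[track.index.min() : track.index.max()]
            rl_ts = SpectrumTimeSeries(
                timestamps=pd.DatetimeIndex(window.index),
                levels=window.to_numpy(dtype=float),
                grid=grid,
            )
            tl = tl_along_track(
                env, grid.band_centers, track.index, track["d_m"].to_numpy(), engine
            )
            sl = backpropagate(rl_ts, tl)
            bb_msl = broadband(sl, kind="BB_MSL")
            bb_rl = broadband(rl_ts, kind="BB_RL")
            row = summarize_transit(events, bb_msl, transit_id, direction, strict=strict)
        except FerryNoiseError as exc:
            logger.info("excluding %s: %s", transit_id, exc)
            exclusions.append((transit_id, str(exc)))
            continue
        rows.append(row)
        sl_series[transit_id] = sl
        bb_series[transit_id] = (bb_rl, bb_msl)

    summaries = pd.DataFrame.from_records(rows)
    report = build_report(summaries, exclusions)
    return AnalysisResult(
        summaries=summaries,
        sl_series=sl_series,
        bb_series=bb_series,
        exclusions=exclusions,
        report=report,
    )


def build_report(summaries: pd.DataFrame, exclusions: list | None = None) -> dict:
    """Statistics blocks: mode means, ΔBB fits, KS D, mixed models."""
    report: dict = {
        "n_transits": int(len(summaries)),
        "exclusions": [list(e) for e in (exclusions or [])],
    }
    if summaries.empty:
        return report
    means = mode_means(summaries)
    report["mode_means"] = means.to_dict(orient="records")
    pooled = {}
    for mode, col in (("cpa", "bb_cpa_db"), ("acc", "bb_acc_db")):
        vals = summaries[col].dropna()
        if len(vals) >= 2:
            pooled[mode] = {
                "mean_db": float(vals.mean()),
                "sd_db": float(vals.std(ddof=1)),
                "n": int(len(vals)),
            }
    report["pooled_means"] = pooled
    report["delta_bb"] = {}
    report["ks"] = {}
    report["mixed_models"] = {}
    for direction in summaries["direction"].unique():
        rows = summaries[summaries["direction"] == direction]
        try:
            fit = delta_bb(summaries, direction)
            report["delta_bb"][direction] = {
                "mean_db": fit.fitted_mean,
                "sigma_db": fit.fitted_sigma,
                "n": int(len(fit.deltas)),
            }
        except InsufficientDataError:
            pass
        x = rows["bb_cpa_db"].dropna().to_numpy()
        y = rows["bb_acc_db"].dropna().to_numpy()
        if len(x) and len(y):
            ks = ks_two_sample(x, y)
            report["ks"][direction] = {"D": ks.D, "n_cpa": ks.n1, "n_acc": ks.n2}
        for mode in ("cpa", "acc"):
            try:
                mm = fit_mixed_model(summaries, mode, direction)
            except Exception as exc:  # degenerate designs happen at CPA
                logger.info("mixed model %s/%s skipped: %s", mode, direction, exc)
                continue
            report["mixed_models"][f"{mode}_{direction}"] = {
                "fixed_effects": {
                    term: {
                        "estimate": float(r["estimate"]),
                        "ci_low": float(r["ci_low"]),
                        "ci_high": float(r["ci_high"]),
                        "p_wald": float(r["p_wald"]),
                    }
                    for term, r in mm.fixed_effects.iterrows()
                },
                "random_intercept_variance": mm.random_intercept_variance,
                "residual_variance": mm.residual_variance,
                "n_obs": mm.n_obs,
                "singular": mm.singular,
            }
    return report


def analyze(scenario: Scenario, strict: bool = False) -> AnalysisResult:
    """Analyze an in-memory :class:`~ferrynoise.scenarios.Scenario`."""
    cfg = scenario.config
    dock_lat, dock_lon = _enu_to_latlon(
        cfg.dock_along_route_m, -400.0, cfg.hydrophone_lat, cfg.hydrophone_lon
    )
    return analyze_scenario(
        scenario.ais,
        scenario.currents,
        scenario.rl,
        cfg.env,
        cfg.hydrophone_lat,
        cfg.hydrophone_lon,
        float(dock_lat),
        float(dock_lon),
        grid=cfg.band_grid,
        engine=cfg.make_engine(),
        strict=strict,
    )


def load_scenario_dir(scenario_dir: str | Path):
    """Load a written scenario directory back into analysis inputs."""
    import yaml

    root = Path(scenario_dir)
    env_cfg = yaml.safe_load((root / "environment.yaml").read_text())
    bathy = ()
    bpath = root / env_cfg.get("bathymetry_csv", "bathymetry.csv")
    if bpath.exists():
        b = pd.read_csv(bpath)
        spacing = np.diff(b["range_m"].to_numpy())
        if np.any(np.abs(spacing - 100.0) > 1.0):
            raise FerryNoiseError("bathymetry table must be on a 100-m grid (±1 m)")
        bathy = tuple(zip(b["range_m"], b["depth_m"]))
    env = EnvironmentModel(
        water_sound_speed=env_cfg["c_w"],
        seabed_sound_speed=env_cfg["c_w"] * env_cfg["c_b_ratio"],
        water_column_height=env_cfg["h"],
        hydrophone_height_above_seabed=env_cfg["hydrophone_height"],
        source_depth=env_cfg.get("source_depth", 3.0),
        sediment_density=env_cfg.get("sediment_density", 1700.0),
        sediment_attenuation=env_cfg.get("sediment_attenuation", 0.0),
        bathymetry_profile=bathy,
    )
    ais = pd.read_csv(root / "ais.csv", parse_dates=["timestamp"])
    currents = pd.read_csv(root / "currents.csv", parse_dates=["timestamp"])
    rl = pd.read_csv(root / "rl_spectra.csv", parse_dates=["timestamp"]).set_index("timestamp")
    grid = BandGrid(
        band_edges=tuple(env_cfg["band_edges_hz"]),
        band_centers=tuple(env_cfg["band_centers_hz"]),
    )
    engine = _engine_from_config(
        env,
        env_cfg.get("engine", "pekeris"),
        env_cfg.get("spreading_coefficient", 15.0),
        env_cfg.get("absorption_db_per_km", 0.0),
    )
    return ais, currents, rl, env, env_cfg, grid, engine


def run_analysis(
    scenario_dir: str | Path,
    out_dir: str | Path,
    strict: bool = False,
    plots: bool = False,
    seed: int | None = None,
) -> AnalysisResult:
    """Analyze a scenario directory and write the report artifacts.

    Writes ``transit_summaries.csv`` (the per-transit table), ``stats.json``,
    a plain-text rendering ``stats.txt``, and optionally per-transit
    diagnostic plots (BB_RL, BB_MSL, STW, acceleration vs time with the CPA
    and speed-change markers).
    """
    ais, currents, rl, env, env_cfg, grid, engine = load_scenario_dir(scenario_dir)
    result = analyze_scenario(
        ais,
        currents,
        rl,
        env,
        env_cfg["hydrophone_lat"],
        env_cfg["hydrophone_lon"],
        env_cfg["dock_lat"],
        env_cfg["dock_lon"],
        grid=grid,
        engine=engine,
        strict=strict,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(env_cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    header = {"config_hash": config_hash, "seed": seed if seed is not None else env_cfg.get("seed")}
    result.report["run"] = header
    result.summaries.to_csv(out / "transit_summaries.csv", index=False)
    (out / "stats.json").write_text(json.dumps(result.report, indent=1, default=str))
    (out / "stats.txt").write_text(render_report(result.report))
    if plots:
        _write_plots(result, ais, currents, env_cfg, out / "plots")
    return result


def render_report(report: dict) -> str:
    lines = [
        "Ferry broadband monopole source levels, per operating mode",
        f"transits analyzed: {report.get('n_transits', 0)} "
        f"(excluded: {len(report.get('exclusions', []))})",
        "",
    ]
    for rec in report.get("mode_means", []):
        lines.append(
            f"BB_MSL {rec['mode'].upper():4s} {rec['direction']:9s}: "
            f"{rec['mean_db']:.2f} +- {rec['sd_db']:.2f} dB (n={rec['n']})"
        )
    for mode, rec in report.get("pooled_means", {}).items():
        lines.append(
            f"BB_MSL {mode.upper():4s} pooled   : "
            f"{rec['mean_db']:.2f} +- {rec['sd_db']:.2f} dB (n={rec['n']})"
        )
    lines.append("")
    for direction, rec in report.get("delta_bb", {}).items():
        lines.append(
            f"DeltaBB {direction}: {rec['mean_db']:.2f} +- {rec['sigma_db']:.2f} dB "
            f"(n={rec['n']})"
        )
    for direction, rec in report.get("ks", {}).items():
        lines.append(f"KS D {direction}: {rec['D']:.3f}")
    for key, mm in report.get("mixed_models", {}).items():
        lines.append(f"mixed model {key} (n={mm['n_obs']}):")
        for term, r in mm["fixed_effects"].items():
            lines.append(
                f"  {term:9s} {r['estimate']:8.3f} "
                f"[{r['ci_low']:.3f}, {r['ci_high']:.3f}] p={r['p_wald']:.3g}"
            )
    return "\n".join(lines) + "\n"


def _write_plots(result: AnalysisResult, ais, currents, env_cfg, plot_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    for _, row in result.summaries.iterrows():
        tid = row["transit_id"]
        if tid not in result.bb_series:
            continue
        bb_rl, bb_msl = result.bb_series[tid]
        records = ais[ais["transit_id"] == tid]
        track = build_track(
            records, currents, env_cfg["hydrophone_lat"], env_cfg["hydrophone_lon"]
        )
        fig, axes = plt.subplots(4, 1, figsize=(7, 9), sharex=True)
        axes[0].plot(bb_rl.timestamps, bb_rl.bb, "k-")
        axes[0].set_ylabel("BB_RL [dB re 1 uPa]")
        axes[1].plot(bb_msl.timestamps, bb_msl.bb, "k-")
        axes[1].set_ylabel("BB_MSL [dB re 1 uPa m]")
        axes[2].plot(track.index, track["stw_kn"], "k-")
        axes[2].set_ylabel("STW [kn]")
        axes[3].plot(track.index, track["a_kn_per_min"], "k-")
        axes[3].axhline(0.0, color="gray", lw=0.8)
        axes[3].set_ylabel("a [kn/min]")
        for ax in axes:
            ax.axvline(row["t_cpa"], color="tab:blue", lw=1)
            ax.axvline(row["t_acc"], color="tab:red", lw=1)
        fig.suptitle(f"{tid} ({row['direction']})")
        fig.tight_layout()
        fig.savefig(plot_dir / f"{tid}.png", dpi=110)
        plt.close(fig)
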