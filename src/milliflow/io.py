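"""Schema-checked table I/O, run configuration, and the staged pipeline.

CSV tables are UTF-8, dot-decimal, header-row mandatory; units are encoded
in the column names (``y_um``, ``shear_mPa``, ...).  Fitted results are
written as JSON with a provenance block (package version, seed, config
hash) so a run can be reproduced byte-for-byte from its bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import photometry, synthetic, velocimetry
from .errors import InvalidInputError, SchemaError
from .hydrodynamics import (
    DEFAULT_SHEAR_TRUNCATION,
    DEFAULT_VELOCITY_TRUNCATION,
    ChannelGeometry,
    FlowDrive,
    ROILayout,
    bottom_shear_profile,
    roi_mean_bottom_shear,
)
from .oxygen import calibrate_stern_volmer, po2_from_intensity

logger = logging.getLogger(__name__)

SCHEMAS: dict[str, list[str]] = {
    "trails": ["x_um", "y_um", "z_um", "trail_length_um", "in_focus"],
    "velocities": ["y_um", "z_um", "v_um_per_s"],
    "roi_series": ["time_h", "roi_index", "intensity"],
    "calibration": ["a_true", "a_measured"],
    "colonization": ["shear_mPa", "colonized"],
    "o2": ["time_h", "intensity"],
}


def _check_schema(df: pd.DataFrame, schema: str) -> None:
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    for col in SCHEMAS[schema]:
        if col not in df.columns:
            raise SchemaError(f"schema {schema!r}: missing column {col!r}")
    for col in SCHEMAS[schema]:
        s = df[col]
        if s.dtype == object:
            sample = s.astype(str).head(50)
            if sample.str.contains(",").any():
                raise SchemaError(
                    f"column {col!r} contains decimal commas; tables must "
                    "use dot-decimal notation")
            raise SchemaError(f"column {col!r} is not numeric")


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named column schema."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    _check_schema(df, schema)
    return df


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Schema-validate then write CSV (UTF-8, dot-decimal, no index)."""
    _check_schema(df, schema)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def _package_version() -> str:
    try:
        return version("milliflow")
    except PackageNotFoundError:
        return "unknown"


def provenance(config: dict, seed: int) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "milliflow_version": _package_version(),
        "seed": int(seed),
    }


def geometry_from_config(cfg: dict) -> tuple[ChannelGeometry, FlowDrive]:
    geom = ChannelGeometry.from_um(cfg["height_um"], cfg["width_um"],
                                   cfg.get("length_mm", 30.0))
    drive = FlowDrive.from_ml_per_h(geom, cfg.get("flow_rate_ml_per_h", 1.0),
                                    cfg.get("viscosity_mPa_s", 1.0) * 1e-3)
    return geom, drive


def shear_map_table(cfg: dict, roi_summary: bool = False) -> pd.DataFrame:
    """Bottom shear profile (y_um, sigma_mPa), optionally per-ROI means."""
    geom, drive = geometry_from_config(cfg)
    trunc = cfg.get("truncation_shear", DEFAULT_SHEAR_TRUNCATION)
    profile = bottom_shear_profile(geom, drive,
                                   step=cfg.get("step_um", 5.0) * 1e-6,
                                   truncation=trunc)
    df = pd.DataFrame({"y_um": profile.y * 1e6,
                       "sigma_mPa": profile.sigma * 1e3})
    if roi_summary:
        layout = ROILayout(roi_width=cfg.get("roi_width_um", 40.0) * 1e-6,
                           n_rois=cfg.get("n_rois", 10))
        df.attrs["roi_means_mPa"] = {
            i: roi_mean_bottom_shear(geom, drive, layout, i, trunc) * 1e3
            for i in range(1, layout.n_rois + 1)}
    return df


ALL_STAGES = ("simulate", "velocimetry", "photometry", "threshold", "oxygen")


def run_pipeline(config: dict, seed: int, outdir) -> dict:
    """Execute the selected stages end to end on synthetic inputs.

    simulate -> velocimetry (trails to field fit) -> photometry (growth
    rates, lags, mode, front) -> threshold -> oxygen.  Per-stage record
    counts and exclusions are logged; the result bundle (JSON + CSVs) is
    deterministic for a given config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise InvalidInputError(f"unknown stages {sorted(unknown)}")
    results: dict = {"provenance": provenance(config, seed)}
    geom_cfg = config.get("geometry", {"height_um": 1000, "width_um": 1000})
    geom, drive = geometry_from_config(geom_cfg)

    if "simulate" in stages:
        trails, trail_truth = synthetic.gen_trail_table(
            geom, geom_cfg.get("flow_rate_ml_per_h", 1.0),
            seed=seed, **config.get("trails", {}))
        write_table(trails, outdir / "trails.csv", "trails")
        growth, growth_truth = synthetic.gen_growth_series(
            seed=seed, **config.get("growth", {}))
        write_table(growth, outdir / "roi_series.csv", "roi_series")
        colonization, col_truth = synthetic.gen_colonization(
            seed=seed, **config.get("colonization", {}))
        write_table(colonization, outdir / "colonization.csv", "colonization")
        o2df, o2_truth = synthetic.gen_oxygen_scenario(
            seed=seed, **config.get("oxygen", {}))
        write_table(o2df, outdir / "o2.csv", "o2")
        cal = synthetic.detection_calibration(
            config.get("growth", {}).get("saturation_scale",
                                         synthetic.SATURATION_SCALE))
        write_table(cal.to_table(), outdir / "calibration.csv", "calibration")
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump({"trails": trail_truth, "growth": growth_truth,
                       "colonization": col_truth, "oxygen": o2_truth},
                      fh, indent=1, sort_keys=True)
        logger.info("simulate: wrote %d trails, %d ROI frames, %d records",
                    len(trails), len(growth), len(colonization))

    if "velocimetry" in stages:
        trails = read_table(outdir / "trails.csv", "trails")
        samples = velocimetry.trails_to_velocities(trails)
        write_table(samples, outdir / "velocities.csv", "velocities")
        fit = velocimetry.fit_field(samples, geom, drive,
                                    tuple(config.get("free_params", ("h", "Q"))),
                                    config.get("truncation_velocity",
                                               DEFAULT_VELOCITY_TRUNCATION))
        results["velocimetry"] = {
            "estimates": {k: float(v) for k, v in fit.params.items()},
            "ci95": {k: float(v) for k, v in fit.ci95.items()},
            "r2": fit.r_squared, "n_used": fit.n_used,
            "n_excluded": fit.n_excluded, "truncation": fit.truncation,
        }

    if "photometry" in stages:
        series = read_table(outdir / "roi_series.csv", "roi_series")
        cal = photometry.CalibrationCurve.from_table(
            read_table(outdir / "calibration.csv", "calibration"))
        i0 = config.get("growth", {}).get("i0", synthetic.I0_DEFAULT)
        layout = ROILayout()
        per_roi, positions, lags = {}, [], []
        for roi, grp in series.groupby("roi_index"):
            ts = photometry.ROITimeSeries(int(roi), grp["time_h"].to_numpy(),
                                          grp["intensity"].to_numpy(), i0)
            corrected = ts.corrected_absorbance(cal)
            lag = photometry.lag_time(ts.times_h, corrected)
            entry = {"delta_h": lag.delta_h, "lag_reached": lag.reached}
            try:
                gfit = photometry.fit_exponential_growth(ts, cal)
                entry.update(mu_per_h=gfit.mu_per_h, r2=gfit.r_squared,
                             n_points=gfit.n_points)
            except photometry.FitWindowError as exc:
                entry["fit_error"] = str(exc)
            per_roi[int(roi)] = entry
            if lag.reached:
                positions.append(layout.right_boundary_um(int(roi)))
                lags.append(lag.delta_h)
        results["photometry"] = {"per_roi": per_roi}
        if len(lags) >= 5:
            mode = photometry.classify_growth_mode(positions, lags)
            results["photometry"]["mode"] = mode
            fk = photometry.front_kinematics(positions, lags)
            if not fk.no_front:
                results["photometry"]["front"] = {
                    "velocity_um_per_day": fk.velocity * 24.0,
                    "se_um_per_day": fk.velocity_se * 24.0,
                    "r2": fk.r_squared,
                }

    if "threshold" in stages:
        records = read_table(outdir / "colonization.csv", "colonization")
        est = photometry.estimate_shear_threshold(records)
        results["threshold"] = {
            "threshold_mPa": est.threshold_mpa,
            "uncertainty_mPa": est.uncertainty_mpa,
            "separable": est.separable,
            "rank_p_value": est.rank_p_value,
        }

    if "oxygen" in stages:
        o2df = read_table(outdir / "o2.csv", "o2")
        o2cfg = config.get("oxygen_calibration",
                           {"i_zero": 2000.0, "i_ref": 1000.0,
                            "po2_ref": 20.0})
        cal = calibrate_stern_volmer(o2cfg["i_zero"], o2cfg["i_ref"],
                                     o2cfg.get("po2_ref", 20.0))
        po2 = po2_from_intensity(o2df["intensity"].to_numpy(), cal)
        out = pd.DataFrame({"time_h": o2df["time_h"], "po2_percent": po2})
        out.to_csv(outdir / "po2.csv", index=False)
        results["oxygen"] = {"k_sv": cal.k_sv,
                             "po2_mean": float(np.mean(po2))}

    with open(outdir / "results.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    return results
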