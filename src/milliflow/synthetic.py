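"""Synthetic measurement generator for every pipeline stage.

Each generator emulates one arm of the millifluidic study with the
statistical structure the downstream analysis assumes, and returns both
the observable table and a truth dictionary echoing every planted
parameter, so recovery can be scored without reading generator code.

Defaults reproduce the study conditions: five channels 250-1000 um high
and 1 mm wide under 1 mL/h; 1 um tracer beads imaged at 40 ms exposure on
a 5 um z-grid; ROI intensity traces at 30 frames/h over 20 h against a
reference level I0 = 2000 grey values with a saturating detection
response; a sharp ~11 mPa colonization threshold on the 5x10 ROI shear
grid; Stern-Volmer quenched oxygen traces.  All randomness flows from one
integer seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import oxygen as o2mod
from .errors import InvalidInputError
from .hydrodynamics import (
    ChannelGeometry,
    FlowDrive,
    ROILayout,
    roi_mean_bottom_shear,
    velocity_at,
)
from .photometry import CalibrationCurve

# acquisition constants of the instrument being emulated
T_ACQ = 0.040  # s
BEAD_DIAMETER_UM = 1.0
Z_SPACING_UM = 5.0
FRAMES_PER_H = 30.0
DURATION_H = 20.0
I0_DEFAULT = 2000.0
INTENSITY_NOISE_SD = 2.0  # grey levels on a ROI-averaged signal
SATURATION_SCALE = 10.0  # corrected-absorbance units
FIVE_CHANNEL_HEIGHTS_UM = (250.0, 350.0, 500.0, 750.0, 1000.0)
TRUTH_TRUNCATION = 50  # series order used to plant "exact" fields


@dataclass
class SimulationConfig:
    """Scenario-independent knobs; per-scenario extras ride in ``extra``."""

    scenario: str  # trails | growth | colonization | oxygen
    seed: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in ("trails", "growth", "colonization", "oxygen"):
            raise InvalidInputError(f"unknown scenario {self.scenario!r}")
        if self.seed is None:
            raise InvalidInputError("a seed is mandatory")


def gen_trail_table(geometry: ChannelGeometry | None = None,
                    flow_rate_ml_h: float = 1.0,
                    viscosity: float = 1.0e-3,
                    n_trails: int = 500,
                    noise_um: float = 0.0,
                    out_of_focus_fraction: float = 0.0,
                    z_spacing_um: float = Z_SPACING_UM,
                    t_acq: float = T_ACQ,
                    bead_diameter_um: float = BEAD_DIAMETER_UM,
                    seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Particle trails painted by the analytic field during one exposure.

    Bead positions sample the open cross-section uniformly in y and on the
    acquisition z-grid; trail length l = v t_acq + bead diameter (+ Gaussian
    length noise).  Out-of-focus trails (flagged 0) get corrupted lengths,
    emulating defocused streaks that the focus filter must drop.
    """
    geometry = geometry or ChannelGeometry.from_um(1000, 1000)
    drive = FlowDrive.from_ml_per_h(geometry, flow_rate_ml_h, viscosity)
    rng = np.random.default_rng(seed)
    w_um = geometry.width * 1e6
    h_um = geometry.height * 1e6
    z_levels = np.arange(z_spacing_um, h_um, z_spacing_um)
    y_um = rng.uniform(0.02 * w_um, 0.98 * w_um, n_trails)
    z_um = rng.choice(z_levels, n_trails)
    v_um_s = velocity_at(geometry, drive, y_um * 1e-6, z_um * 1e-6,
                         truncation=TRUTH_TRUNCATION) * 1e6
    length = v_um_s * t_acq + bead_diameter_um
    if noise_um > 0:
        length = length + rng.normal(0.0, noise_um, n_trails)
    in_focus = np.ones(n_trails, dtype=int)
    if out_of_focus_fraction > 0:
        blurred = rng.random(n_trails) < out_of_focus_fraction
        in_focus[blurred] = 0
        length[blurred] *= rng.uniform(0.2, 0.8, int(blurred.sum()))
    df = pd.DataFrame({
        "x_um": rng.uniform(0.0, geometry.length * 1e6, n_trails),
        "y_um": y_um,
        "z_um": z_um,
        "trail_length_um": np.maximum(length, 0.0),
        "in_focus": in_focus,
    })
    truth = {
        "height_um": h_um, "width_um": w_um,
        "flow_rate_ml_per_h": flow_rate_ml_h,
        "viscosity_mPa_s": viscosity * 1e3,
        "t_acq_s": t_acq, "bead_diameter_um": bead_diameter_um,
        "noise_um": noise_um, "out_of_focus_fraction": out_of_focus_fraction,
        "n_trails": n_trails, "seed": int(seed),
    }
    return df, truth


def gen_growth_series(mode: str = "uniform",
                      mu_per_h: float = 0.5,
                      lag_edge_h: float = 5.0,
                      front_velocity_um_per_day: float = 529.0,
                      f0: float = 0.02,
                      layout: ROILayout | None = None,
                      duration_h: float = DURATION_H,
                      frames_per_h: float = FRAMES_PER_H,
                      i0: float = I0_DEFAULT,
                      intensity_noise: float = INTENSITY_NOISE_SD,
                      saturation_scale: float = SATURATION_SCALE,
                      seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """ROI intensity traces under exponential biomass growth.

    True corrected absorbance per ROI: a_i(t) = f0 exp(mu (t - delta_i))
    for t >= delta_i, zero before.  Lags are constant (uniform mode) or
    increase linearly with the ROI's distance from the channel edge
    (advancing front at the planted velocity).  Detection saturates as
    A_meas = s (1 - exp(-a/s)); intensity I = I0 exp(-A_meas) plus Gaussian
    camera noise on the ROI-averaged grey level.
    """
    if mode not in ("uniform", "advancing_front"):
        raise InvalidInputError(f"unknown growth mode {mode!r}")
    layout = layout or ROILayout()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h, 1.0 / frames_per_h)
    rows = []
    lags = {}
    for roi in range(1, layout.n_rois + 1):
        y_um = layout.right_boundary_um(roi)
        if mode == "uniform":
            delta = lag_edge_h
        else:
            delta = lag_edge_h + y_um / (front_velocity_um_per_day / 24.0)
        lags[roi] = float(delta)
        a_true = np.where(times >= delta,
                          f0 * np.exp(mu_per_h * (times - delta)), 0.0)
        a_meas = saturation_scale * (1.0 - np.exp(-a_true / saturation_scale))
        intensity = i0 * np.exp(-a_meas)
        if intensity_noise > 0:
            intensity = intensity + rng.normal(0.0, intensity_noise, times.size)
        rows.append(pd.DataFrame({
            "time_h": times,
            "roi_index": roi,
            "intensity": np.maximum(intensity, 1.0),
        }))
    df = pd.concat(rows, ignore_index=True)
    truth = {
        "mode": mode, "mu_per_h": mu_per_h, "f0": f0,
        "lag_edge_h": lag_edge_h, "lags_h": lags,
        "front_velocity_um_per_day": (front_velocity_um_per_day
                                      if mode == "advancing_front" else None),
        "i0": i0, "intensity_noise": intensity_noise,
        "saturation_scale": saturation_scale,
        "frames_per_h": frames_per_h, "duration_h": duration_h,
        "roi_width_um": layout.roi_width * 1e6, "n_rois": layout.n_rois,
        "seed": int(seed),
    }
    return df, truth


def detection_calibration(saturation_scale: float = SATURATION_SCALE,
                          **kwargs) -> CalibrationCurve:
    """Calibration table matching the generator's saturating response."""
    return CalibrationCurve.from_saturating_map(saturation_scale, **kwargs)


def gen_colonization(threshold_mpa: float = 11.0,
                     heights_um: tuple = FIVE_CHANNEL_HEIGHTS_UM,
                     width_um: float = 1000.0,
                     flow_rate_ml_h: float = 1.0,
                     viscosity: float = 1.0e-3,
                     layout: ROILayout | None = None,
                     flip_scale_mpa: float = 0.0,
                     seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Threshold-governed colonization outcomes on the multi-channel ROI grid.

    Each ROI of each channel gets its mean bottom shear from the analytic
    profile; attachment succeeds where shear < threshold.  A positive
    ``flip_scale_mpa`` softens the rule into a logistic flip probability
    around the threshold, emulating stochastic attachment near it.
    """
    if threshold_mpa <= 0:
        raise InvalidInputError("threshold must be positive")
    layout = layout or ROILayout()
    rng = np.random.default_rng(seed)
    records = []
    for h_um in heights_um:
        geom = ChannelGeometry.from_um(h_um, width_um)
        drive = FlowDrive.from_ml_per_h(geom, flow_rate_ml_h, viscosity)
        for roi in range(1, layout.n_rois + 1):
            shear_mpa = roi_mean_bottom_shear(geom, drive, layout, roi) * 1e3
            if flip_scale_mpa > 0:
                p_col = 1.0 / (1.0 + np.exp(
                    (shear_mpa - threshold_mpa) / flip_scale_mpa))
                colonized = bool(rng.random() < p_col)
            else:
                colonized = bool(shear_mpa < threshold_mpa)
            records.append({
                "channel_id": f"h{int(h_um)}",
                "height_um": h_um,
                "roi_index": roi,
                "shear_mPa": shear_mpa,
                "colonized": colonized,
            })
    df = pd.DataFrame(records)
    truth = {
        "threshold_mPa": threshold_mpa, "flip_scale_mPa": flip_scale_mpa,
        "heights_um": list(heights_um), "width_um": width_um,
        "flow_rate_ml_per_h": flow_rate_ml_h, "seed": int(seed),
    }
    return df, truth


def gen_oxygen_series(po2_percent,
                      times_h=None,
                      i_zero: float = 2000.0,
                      k_sv: float = 0.05,
                      noise: float = 0.0,
                      seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Quenched-probe intensity trace for a planted pO2 schedule."""
    po2 = np.asarray(po2_percent, dtype=float)
    if times_h is None:
        times_h = np.arange(po2.size, dtype=float)
    cal = o2mod.O2Calibration(i_zero=i_zero, k_sv=k_sv)
    rng = np.random.default_rng(seed)
    intensity = np.asarray(o2mod.intensity_from_po2(po2, cal))
    if noise > 0:
        intensity = np.maximum(intensity + rng.normal(0.0, noise, po2.size), 1.0)
    df = pd.DataFrame({"time_h": np.asarray(times_h, dtype=float),
                       "intensity": intensity})
    truth = {"po2_percent": po2.tolist(), "i_zero": i_zero, "k_sv": k_sv,
             "noise": noise, "seed": int(seed)}
    return df, truth


def simulate(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Dispatch a scenario; ``config.extra`` passes generator kwargs."""
    gen = {
        "trails": gen_trail_table,
        "growth": gen_growth_series,
        "colonization": gen_colonization,
        "oxygen": gen_oxygen_scenario,
    }[config.scenario]
    return gen(seed=config.seed, **config.extra)


def gen_oxygen_scenario(seed: int = 0, **extra):
    """Oxygen generator with a default two-level (5.0% -> 1.2%) schedule."""
    extra.setdefault("po2_percent", [5.0] * 10 + [1.2] * 10)
    return gen_oxygen_series(seed=seed, **extra)
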