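"""Particle-streak velocimetry: trails to velocities, field fitting.

During a long camera exposure (default 40 ms) a tracer bead of diameter d
moving at speed v paints a linear streak of length l = v t_acq + d on the
image; inverting that arithmetic per trail gives one velocity sample at the
trail's (y, z) position.  The sample cloud is then fitted to the analytic
rectangular-duct field by nonlinear least squares with a chosen set of free
parameters — effective height h (biofilm carpet on the bottom), effective
width w and no-slip offset y0 (advancing lateral fronts), and optionally
the flow rate Q — yielding effective geometries, biofilm thicknesses, 95%
confidence intervals and R^2 diagnostics.

Velocities are um/s in this module (native trail units); positions um.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    FitConvergenceError,
    IdentifiabilityError,
    InvalidInputError,
)
from .hydrodynamics import (
    DEFAULT_VELOCITY_TRUNCATION,
    ChannelGeometry,
    FlowDrive,
    velocity_at,
)

logger = logging.getLogger(__name__)

DEFAULT_T_ACQ = 0.040  # s
DEFAULT_BEAD_DIAMETER_UM = 1.0

_FREE_PARAM_SETS = (
    ("h",),
    ("h", "Q"),
    ("w", "y0"),
    ("w", "y0", "Q"),
)


def trails_to_velocities(trails: pd.DataFrame,
                         t_acq: float = DEFAULT_T_ACQ,
                         bead_diameter_um: float = DEFAULT_BEAD_DIAMETER_UM,
                         focus_filter: bool = True) -> pd.DataFrame:
    """Convert a trail table to velocity samples, v = (l - d) / t_acq.

    ``trails`` needs columns ``y_um, z_um, trail_length_um`` and, when
    ``focus_filter`` is on, ``in_focus`` (0/1).  Out-of-focus trails and
    trails shorter than the bead diameter are dropped; the counts are
    logged and attached to the result as ``attrs['n_out_of_focus']`` and
    ``attrs['n_too_short']``.
    """
    if t_acq <= 0:
        raise InvalidInputError("acquisition time must be positive")
    df = trails
    n_in = len(df)
    n_focus = 0
    if focus_filter and "in_focus" in df.columns:
        kept = df[df["in_focus"].astype(bool)]
        n_focus = n_in - len(kept)
        df = kept
    short = df["trail_length_um"] < bead_diameter_um
    n_short = int(short.sum())
    df = df[~short]
    out = pd.DataFrame({
        "y_um": df["y_um"].to_numpy(dtype=float),
        "z_um": df["z_um"].to_numpy(dtype=float),
        "v_um_per_s": (df["trail_length_um"].to_numpy(dtype=float)
                       - bead_diameter_um) / t_acq,
    })
    out.attrs["n_out_of_focus"] = n_focus
    out.attrs["n_too_short"] = n_short
    logger.info("trails_to_velocities: %d in, %d out-of-focus, %d sub-bead, %d kept",
                n_in, n_focus, n_short, len(out))
    return out


@dataclass
class FieldFit:
    """Result of fitting velocity samples to the duct field."""

    free: tuple[str, ...]
    params: dict[str, float]  # h, w in m; y0 in m; Q in m^3/s
    ci95: dict[str, float]  # half-widths, same units
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    n_used: int = 0
    n_excluded: int = 0
    truncation: int = DEFAULT_VELOCITY_TRUNCATION
    cost: float = 0.0

    def __post_init__(self):
        for k, v in self.params.items():
            if k in ("h", "w") and v <= 0:
                raise InvalidInputError(f"fitted {k} must be positive, got {v}")


def _model_velocity_um_s(y_um, z_um, *, h, w, y0, q, viscosity, truncation):
    """Duct field in um/s; zero outside the effective open cross-section."""
    geom = ChannelGeometry(h, w)
    drive = FlowDrive.from_flow_rate(geom, q, viscosity)
    y = y_um * 1e-6 - y0
    z = z_um * 1e-6
    inside = (y >= 0) & (y <= w) & (z >= 0) & (z <= h)
    v = np.zeros_like(np.asarray(y, dtype=float))
    if inside.any():
        v[inside] = velocity_at(geom, drive, y[inside], z[inside], truncation)
    return v * 1e6


def fit_field(samples: pd.DataFrame,
              geometry: ChannelGeometry,
              drive: FlowDrive,
              free_params: tuple[str, ...] = ("h", "Q"),
              truncation: int = DEFAULT_VELOCITY_TRUNCATION,
              multistart: bool = True,
              xtol: float = 1e-10) -> FieldFit:
    """Least-squares fit of the analytic field over the chosen free set.

    ``free_params`` is one of {h}, {h, Q}, {w, y0}, {w, y0, Q}.  Fixed
    parameters stay at their nominal (``geometry``/``drive``) values.  With
    free (w, y0), sample coordinates are mapped onto an effective duct with
    no-slip walls at y0 and y0 + w; samples landing outside it after the
    first pass are excluded and the fit repeated once (``n_excluded``).
    95% confidence intervals come from the Jacobian-based covariance at the
    optimum; R^2 from the retained residuals.
    """
    free = tuple(free_params)
    if free not in _FREE_PARAM_SETS:
        raise InvalidInputError(
            f"free_params must be one of {_FREE_PARAM_SETS}, got {free}")
    y_um = samples["y_um"].to_numpy(dtype=float)
    z_um = samples["z_um"].to_numpy(dtype=float)
    v_obs = samples["v_um_per_s"].to_numpy(dtype=float)
    weights = (samples["weight"].to_numpy(dtype=float)
               if "weight" in samples.columns else None)
    if len(v_obs) < 3 * len(free):
        raise InvalidInputError(
            f"{len(v_obs)} samples cannot constrain {len(free)} parameters "
            "(need >= 3x)")
    if "h" in free and np.unique(z_um).size < 2:
        raise IdentifiabilityError(
            "free height needs samples at more than one z level")

    nominal = {
        "h": geometry.height,
        "w": geometry.width,
        "y0": 0.1 * geometry.width,  # a 0 start would pin the scaled step
        "Q": drive.flow_rate,
    }
    scales = {"h": geometry.height, "w": geometry.width,
              "y0": geometry.width, "Q": drive.flow_rate}

    def unpack(x, mask=None):
        p = {"h": geometry.height, "w": geometry.width, "y0": 0.0,
             "q": drive.flow_rate}
        for name, xi in zip(free, x):
            key = "q" if name == "Q" else name
            p[key] = xi * scales[name]
        return p

    def residuals(x, mask):
        p = unpack(x)
        pred = _model_velocity_um_s(y_um[mask], z_um[mask],
                                    viscosity=drive.viscosity,
                                    truncation=truncation, **p)
        r = pred - v_obs[mask]
        if weights is not None:
            r = r * np.sqrt(weights[mask])
        return r

    def solve(mask):
        x0_base = np.array([nominal[name] / scales[name] for name in free])
        starts = [x0_base]
        if multistart:
            for combo in itertools.product((0.8, 1.2), repeat=len(free)):
                starts.append(x0_base * np.array(combo))
        best = None
        for x0 in starts:
            try:
                res = optimize.least_squares(
                    residuals, x0, args=(mask,), method="trf",
                    xtol=xtol, ftol=1e-12, gtol=1e-12,
                    bounds=(1e-6, np.inf))
            except Exception:  # singular start, occluded trial geometry...
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None or not best.success:
            raise FitConvergenceError(
                "field fit did not converge",
                best_params=None if best is None else unpack(best.x))
        return best

    mask = np.ones(len(v_obs), dtype=bool)
    res = solve(mask)
    n_excluded = 0
    if "w" in free or "y0" in free:
        p = unpack(res.x)
        y_m = y_um * 1e-6 - p["y0"]
        inside = (y_m >= 0) & (y_m <= p["w"])
        n_excluded = int((~inside).sum())
        if n_excluded:
            logger.info("fit_field: excluding %d samples outside the "
                        "effective duct and refitting", n_excluded)
            mask = inside
            res = solve(mask)

    p = unpack(res.x)
    params = {name: p["q" if name == "Q" else name] for name in free}
    n_used = int(mask.sum())
    dof = n_used - len(free)
    ssr = float(2.0 * res.cost)
    # covariance of the scaled parameters from the Jacobian at the optimum
    jtj = res.jac.T @ res.jac
    try:
        cov_scaled = np.linalg.inv(jtj) * (ssr / dof if dof > 0 else np.nan)
    except np.linalg.LinAlgError:
        cov_scaled = np.full((len(free), len(free)), np.nan)
    tval = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    ci95 = {name: float(tval * np.sqrt(cov_scaled[i, i]) * scales[name])
            for i, name in enumerate(free)}
    v_used = v_obs[mask]
    sst = float(((v_used - v_used.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    return FieldFit(free=free, params=params, ci95=ci95, r_squared=r2,
                    residuals=res.fun.copy(), n_used=n_used,
                    n_excluded=n_excluded, truncation=truncation, cost=ssr)


def fit_height_series_best_q(sample_sets: list[pd.DataFrame],
                             geometry: ChannelGeometry,
                             drive: FlowDrive,
                             q_candidates: np.ndarray,
                             truncation: int = DEFAULT_VELOCITY_TRUNCATION,
                             ) -> tuple[float, list[FieldFit], dict[float, float]]:
    """Per-time-point free-h fits at candidate fixed flow rates.

    For each candidate Q, every sample set is fitted with only the height
    free; the Q minimizing the summed squared residuals over all time
    points wins.  Returns (best Q in m^3/s, the fits at that Q, the total
    SSR per candidate).
    """
    totals: dict[float, float] = {}
    fits_by_q: dict[float, list[FieldFit]] = {}
    for q in np.asarray(q_candidates, dtype=float):
        d = FlowDrive.from_flow_rate(geometry, q, drive.viscosity)
        fits = [fit_field(s, geometry, d, free_params=("h",),
                          truncation=truncation) for s in sample_sets]
        totals[float(q)] = float(sum(f.cost for f in fits))
        fits_by_q[float(q)] = fits
    best_q = min(totals, key=totals.get)
    return best_q, fits_by_q[best_q], totals


def biofilm_thickness_series(fits: list[FieldFit], nominal_h: float,
                             times: np.ndarray | None = None) -> pd.DataFrame:
    """Thickness(t) = nominal height minus fitted effective height.

    Confidence half-widths carry over unchanged (the nominal height is
    treated as exact).  A fitted height above nominal gives a negative
    thickness which is reported as 0 with ``flagged = True``; monotone
    decrease of the effective height is reported, never enforced.
    """
    rows = []
    for i, f in enumerate(fits):
        if "h" not in f.params:
            raise InvalidInputError("all fits must have free height")
        h_eff = f.params["h"]
        thickness = nominal_h - h_eff
        flagged = thickness < 0
        if flagged:
            logger.warning("fit %d: effective height %.3g m above nominal; "
                           "thickness clipped to 0", i, h_eff)
        rows.append({
            "time_h": np.nan if times is None else float(times[i]),
            "h_eff_m": h_eff,
            "thickness_m": max(thickness, 0.0),
            "ci95_m": f.ci95.get("h", np.nan),
            "flagged": flagged,
        })
    return pd.DataFrame(rows)
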