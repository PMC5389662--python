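"""Microphotometric biomass quantification and growth kinetics.

Transmitted-light image intensity is turned into a biomass proxy through a
Beer-Lambert-type microscopic absorbance A = ln(I0/I), where I0 is the
grey level of the biofilm-free channel.  Because the detector response
saturates at high optical density, measured absorbance is first inverted
through an empirically tabulated calibration curve ("corrected
absorbance"), then converted to surfacic cell density (cells/mm^2) or a
per-channel cell count.  On the corrected curves this module extracts:

* the growth rate mu from an exponential fit f(t) = f0 exp(mu t),
* the lag time delta, the first upward crossing of a small absorbance
  threshold (default 0.02, above noise yet early in growth),
* front kinematics — in the advancing-front mode the lag grows linearly
  with distance from the channel edge and the inverse slope is the front
  velocity,
* a uniform vs advancing-front growth-mode classification,
* the colonization shear-stress threshold separating surface regions that
  ever initiate biofilm from those that never do, and
* the lag-vs-shear relation in the sub-threshold regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator

from .errors import (
    CalibrationError,
    FitWindowError,
    InvalidInputError,
    ThresholdUndefinedError,
)

logger = logging.getLogger(__name__)

DEFAULT_LAG_THRESHOLD = 0.02
DEFAULT_CUTOFF = 0.74
DEFAULT_SATURATION_ONSET = 0.7
DEFAULT_A_N = 1.1e-9  # absorbance per cell in the channel
DEFAULT_C_S = 3.0e7  # cells per mm^2 per absorbance unit
CHANNEL_BOTTOM_AREA_MM2 = 30.0
DEFAULT_FRAMES_PER_H = 30.0


def absorbance(intensity, i0):
    """Microscopic absorbance A = ln(I0 / I)."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0) or i0 <= 0:
        raise InvalidInputError("intensities must be positive")
    out = np.log(i0 / intensity)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class CalibrationCurve:
    """Tabulated true-vs-measured absorbance map plus conversion constants.

    ``true_values`` / ``measured_values`` trace the saturating detector
    response (both strictly increasing, anchored at 0); ``a_n`` is the
    absorbance contributed per cell in the channel, ``c_s`` the surfacic
    density per absorbance unit, mutually consistent through the channel
    bottom area: c_s ~ 1 / (a_n * area).
    """

    true_values: np.ndarray
    measured_values: np.ndarray
    a_n: float = DEFAULT_A_N
    c_s: float = DEFAULT_C_S
    saturation_onset: float = DEFAULT_SATURATION_ONSET
    cutoff: float = DEFAULT_CUTOFF
    bottom_area_mm2: float = CHANNEL_BOTTOM_AREA_MM2

    def __post_init__(self):
        t = np.asarray(self.true_values, dtype=float)
        m = np.asarray(self.measured_values, dtype=float)
        if t.shape != m.shape or t.ndim != 1 or t.size < 2:
            raise CalibrationError("calibration table must be two matched 1-D columns")
        if np.any(np.diff(t) <= 0) or np.any(np.diff(m) <= 0):
            raise CalibrationError("calibration table must be strictly increasing")
        object.__setattr__(self, "true_values", t)
        object.__setattr__(self, "measured_values", m)

    @classmethod
    def from_table(cls, table: pd.DataFrame, **kwargs) -> "CalibrationCurve":
        return cls(table["a_true"].to_numpy(dtype=float),
                   table["a_measured"].to_numpy(dtype=float), **kwargs)

    @classmethod
    def from_saturating_map(cls, saturation_scale: float = 10.0,
                            a_true_max: float = 1.2, n: int = 400,
                            **kwargs) -> "CalibrationCurve":
        """Tabulate A_meas = s (1 - exp(-a / s)), the generator's response."""
        a = np.linspace(0.0, a_true_max, n)
        m = saturation_scale * (1.0 - np.exp(-a / saturation_scale))
        return cls(a, m, **kwargs)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"a_true": self.true_values,
                             "a_measured": self.measured_values})

    def correct(self, a_measured):
        """Invert the detection map by monotone (PCHIP) interpolation."""
        inv = PchipInterpolator(self.measured_values, self.true_values,
                                extrapolate=False)
        a = np.asarray(a_measured, dtype=float)
        out = inv(np.clip(a, self.measured_values[0], None))
        return out if out.shape else float(out)


def correct_absorbance(a_measured, calibration: CalibrationCurve):
    """Undo detection saturation; NaN for records at or above the cutoff.

    Records with measured absorbance >= the retention cutoff (default 0.74)
    are outside the trusted quasi-linear region and are excluded (returned
    as NaN, count logged).
    """
    a = np.asarray(a_measured, dtype=float)
    excluded = a >= calibration.cutoff
    n_excl = int(excluded.sum())
    if n_excl:
        logger.info("correct_absorbance: excluding %d records at measured "
                    "absorbance >= %.3g", n_excl, calibration.cutoff)
    out = np.where(excluded, np.nan, calibration.correct(np.where(excluded, 0.0, a)))
    return out if out.shape else float(out)


def cells_from_absorbance(a_corrected, calibration: CalibrationCurve):
    """Surfacic density (cells/mm^2) and per-channel count from absorbance."""
    a = np.asarray(a_corrected, dtype=float)
    if np.any(a < 0):
        raise InvalidInputError("corrected absorbance must be >= 0")
    surfacic = calibration.c_s * a
    per_channel = a / calibration.a_n
    if a.shape:
        return surfacic, per_channel
    return float(surfacic), float(per_channel)


@dataclass
class ROITimeSeries:
    """Per-ROI intensity trace with its biofilm-free reference level."""

    roi_index: int
    times_h: np.ndarray
    intensities: np.ndarray
    i0: float = 2000.0

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.intensities <= 0) or self.i0 <= 0:
            raise InvalidInputError("intensities must be positive")

    def measured_absorbance(self) -> np.ndarray:
        return absorbance(self.intensities, self.i0)

    def corrected_absorbance(self, calibration: CalibrationCurve) -> np.ndarray:
        """Corrected trace; NaN marks excluded (saturated) records."""
        return correct_absorbance(self.measured_absorbance(), calibration)


@dataclass
class GrowthFit:
    """Exponential biomass expansion f(t) = f0 exp(mu t) on one ROI."""

    mu_per_h: float
    f0: float
    mu_se: float
    window: tuple[float, float]
    n_points: int
    r_squared: float


def fit_exponential(times_h, values, window: tuple[float, float],
                    min_points: int = 5) -> GrowthFit:
    """Least-squares fit of f0 exp(mu t) on in-window corrected absorbance."""
    t = np.asarray(times_h, dtype=float)
    f = np.asarray(values, dtype=float)
    lo, hi = window
    mask = np.isfinite(f) & (f >= lo) & (f <= hi)
    if mask.sum() < min_points:
        raise FitWindowError(
            f"only {int(mask.sum())} points inside window [{lo:.3g}, {hi:.3g}]"
            f" (need >= {min_points})")
    t_w, f_w = t[mask], f[mask]
    # log-linear start, then nonlinear refinement on the natural scale
    slope, intercept = np.polyfit(t_w, np.log(f_w), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    popt, pcov = optimize.curve_fit(
        lambda tt, f0, mu: f0 * np.exp(mu * tt), t_w, f_w, p0=p0, maxfev=10000)
    f0, mu = popt
    resid = f_w - f0 * np.exp(mu * t_w)
    sst = float(((f_w - f_w.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else np.nan
    return GrowthFit(mu_per_h=float(mu), f0=float(f0),
                     mu_se=float(np.sqrt(pcov[1, 1])),
                     window=(lo, hi), n_points=int(mask.sum()), r_squared=r2)


def fit_exponential_growth(series: ROITimeSeries,
                           calibration: CalibrationCurve,
                           window: tuple[float, float] | None = None,
                           min_points: int = 5) -> GrowthFit:
    """Growth-rate fit on the corrected absorbance of one ROI.

    The default window spans from the lag threshold (0.02) up to the
    corrected value of the retention cutoff, i.e. the exponential phase the
    detector can trust.
    """
    corrected = series.corrected_absorbance(calibration)
    if window is None:
        window = (DEFAULT_LAG_THRESHOLD,
                  float(calibration.correct(calibration.cutoff * (1 - 1e-9))))
    return fit_exponential(series.times_h, corrected, window, min_points)


@dataclass
class LagResult:
    delta_h: float | None
    reached: bool
    started_above: bool = False


def lag_time(times_h, corrected, threshold: float = DEFAULT_LAG_THRESHOLD
             ) -> LagResult:
    """First upward crossing of the lag threshold, frame-interpolated.

    Linear interpolation between the last frame below and the first frame
    at/above the threshold.  A series that never reaches it is flagged
    ``reached=False``; one that starts at/above it returns the first time,
    flagged ``started_above``.
    """
    t = np.asarray(times_h, dtype=float)
    f = np.asarray(corrected, dtype=float)
    ok = np.isfinite(f)
    t, f = t[ok], f[ok]
    if t.size == 0:
        return LagResult(None, reached=False)
    if f[0] >= threshold:
        return LagResult(float(t[0]), reached=True, started_above=True)
    above = np.nonzero(f >= threshold)[0]
    if above.size == 0:
        return LagResult(None, reached=False)
    i = int(above[0])
    frac = (threshold - f[i - 1]) / (f[i] - f[i - 1])
    return LagResult(float(t[i - 1] + frac * (t[i] - t[i - 1])), reached=True)


@dataclass
class FrontKinematics:
    """Linear lag-vs-position fit: constant-velocity colonization front."""

    velocity: float | None  # position units per delta unit
    velocity_se: float | None
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    no_front: bool = False

    def delta_at(self, y: float) -> float:
        return self.intercept + self.slope * y


def front_kinematics(positions, deltas) -> FrontKinematics:
    """OLS line delta = a + b y; front velocity 1/b, se propagated as se_b/b^2.

    A non-positive slope yields a no-front diagnostic (uniform colonization
    suspected) instead of a velocity.
    """
    y = np.asarray(positions, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if y.size < 3:
        raise InvalidInputError("front kinematics needs >= 3 ROI lag points")
    res = stats.linregress(y, d)
    if res.slope <= 0:
        logger.info("front_kinematics: non-positive slope %.3g; no front",
                    res.slope)
        return FrontKinematics(None, None, res.slope, res.intercept,
                               res.rvalue**2, res.pvalue, no_front=True)
    velocity = 1.0 / res.slope
    velocity_se = res.stderr / res.slope**2
    return FrontKinematics(float(velocity), float(velocity_se),
                           float(res.slope), float(res.intercept),
                           float(res.rvalue**2), float(res.pvalue))


def front_delay(front_a: FrontKinematics, front_b: FrontKinematics,
                y: float) -> float:
    """Lag difference between two channels at a common position."""
    return front_a.delta_at(y) - front_b.delta_at(y)


def classify_growth_mode(positions, deltas,
                         p_threshold: float = 0.01,
                         dispersion_multiple: float = 3.0) -> str:
    """'uniform', 'advancing_front', or 'indeterminate' from per-ROI lags.

    Advancing front requires a significantly positive lag-vs-position slope
    (p < ``p_threshold``) AND a lag range exceeding ``dispersion_multiple``
    times the median absolute deviation of the lags.  Without a significant
    slope the bundle is uniform.  Mixed evidence — a significant trend whose
    range stays inside the scatter band, or a significant *negative* trend —
    is reported as indeterminate rather than silently guessed.
    """
    y = np.asarray(positions, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if d.size < 5:
        raise InvalidInputError("mode classification needs >= 5 ROI lags")
    spread = float(d.max() - d.min())
    if spread == 0.0:
        return "uniform"
    mad = float(stats.median_abs_deviation(d))
    wide = spread > dispersion_multiple * mad if mad > 0 else True
    res = stats.linregress(y, d)
    significant = res.pvalue < p_threshold
    if significant and res.slope > 0:
        return "advancing_front" if wide else "indeterminate"
    if significant and res.slope < 0:
        return "indeterminate"
    return "uniform"


@dataclass
class ThresholdEstimate:
    """Colonization shear threshold from colonized/non-colonized records."""

    threshold_mpa: float | None
    uncertainty_mpa: float | None
    separable: bool
    overlap_interval: tuple[float, float] | None
    rank_p_value: float
    n_colonized: int
    n_non_colonized: int


def estimate_shear_threshold(records: pd.DataFrame) -> ThresholdEstimate:
    """Midpoint of the gap between colonized and non-colonized shear ranges.

    ``records`` needs columns ``shear_mPa`` and ``colonized`` (bool/0-1).
    With perfectly separated classes the estimate is the midpoint between
    the largest colonized and smallest non-colonized mean shear, and the
    uncertainty is half that gap.  Overlapping classes yield no point
    estimate but the overlap interval plus a rank-based separation
    diagnostic (one-sided Mann-Whitney U).  Invariant under record order
    and duplication.
    """
    shear = records["shear_mPa"].to_numpy(dtype=float)
    if np.any(shear < 0):
        raise InvalidInputError("mean shear must be >= 0")
    colonized = records["colonized"].to_numpy().astype(bool)
    s_col = shear[colonized]
    s_non = shear[~colonized]
    if s_col.size == 0 or s_non.size == 0:
        raise ThresholdUndefinedError(
            "need at least one colonized and one non-colonized record")
    u = stats.mannwhitneyu(s_col, s_non, alternative="less")
    lo, hi = float(s_col.max()), float(s_non.min())
    if lo < hi:
        return ThresholdEstimate((lo + hi) / 2.0, (hi - lo) / 2.0, True, None,
                                 float(u.pvalue), int(s_col.size),
                                 int(s_non.size))
    logger.info("estimate_shear_threshold: classes overlap on [%.3g, %.3g]",
                hi, lo)
    return ThresholdEstimate(None, None, False, (hi, lo), float(u.pvalue),
                             int(s_col.size), int(s_non.size))


@dataclass
class LagShearRelation:
    """Pearson correlation and exponential fit of lag vs mean shear."""

    correlation: float
    p_value: float
    amplitude: float  # A in delta = A exp(B sigma)
    rate: float  # B, per mPa
    amplitude_se: float
    rate_se: float


def lag_shear_relation(shear_mpa, deltas) -> LagShearRelation:
    """Correlation and delta = A exp(B sigma) fit in the sub-threshold regime."""
    s = np.asarray(shear_mpa, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if s.size < 5:
        raise InvalidInputError("lag-shear relation needs >= 5 pairs")
    if np.ptp(s) == 0 or np.ptp(d) == 0:
        raise InvalidInputError("degenerate variance: correlation undefined")
    r, p = stats.pearsonr(s, d)
    if np.all(d > 0):
        b0, loga = np.polyfit(s, np.log(d), 1)
        p0 = (float(np.exp(loga)), float(b0))
    else:
        p0 = (float(d.mean()), 0.1)
    popt, pcov = optimize.curve_fit(
        lambda x, a, b: a * np.exp(b * x), s, d, p0=p0, maxfev=10000)
    return LagShearRelation(float(r), float(p), float(popt[0]), float(popt[1]),
                            float(np.sqrt(pcov[0, 0])),
                            float(np.sqrt(pcov[1, 1])))
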