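"""Analytic laminar flow and wall shear in a rectangular millifluidic duct.

A Newtonian fluid driven at low Reynolds number through a channel of
rectangular cross-section (width ``w`` across ``y``, height ``h`` across
``z``, flow along ``x``) obeys the Stokes equations with no-slip walls.  The
velocity profile admits the classical double-cosh/cos series solution

    v(y, z) / (4 v1) = (y/w)(1 - y/w) + (z/h)(1 - z/h)
        - sum_n (-1)^n (2 / ((2n+1) pi))^3
            [ cosh(p_n (y - w/2)) / cosh(p_n w/2) * cos(p_n (z - h/2))
            + cosh(q_n (z - h/2)) / cosh(q_n h/2) * cos(q_n (y - w/2)) ]

with wavenumbers ``p_n = (2n+1) pi / h``, ``q_n = (2n+1) pi / w`` and the
velocity scale ``v1 = (G / 8 eta) w^2 h^2 / (w^2 + h^2)`` where
``G = -dp/dx`` is the imposed pressure gradient.  Integrating over the
cross-section gives the volumetric rate

    Q = 4 w h v1 { 1/3 - sum_n (2/((2n+1) pi))^5
                    [ (h/w) tanh(p_n w/2) + (w/h) tanh(q_n h/2) ] }

whose terms decay as 1/(2n+1)^5, so a low truncation order suffices for
velocity and flow-rate work.  The bottom shear stress is the analytic
z-derivative at the glass wall,

    sigma(y) = eta dv/dz|_{z=0} = 4 eta v1 [ 1/h
        - sum_n (2/((2n+1) pi))^3
            ( p_n cosh(p_n (y - w/2)) / cosh(p_n w/2)
            - (-1)^n q_n tanh(q_n h/2) cos(q_n (y - w/2)) ) ]

which converges only as 1/(2n+1)^2; shear evaluation therefore defaults to
a much higher truncation order than velocity evaluation.

Units are SI internally (m, Pa, m^3/s); helpers accept the bench units used
at the instrument (um, mL/h, mPa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError, InvalidInputError, OcclusionError

#: 1 mL/h in m^3/s.
ML_PER_H = 1e-6 / 3600.0

DEFAULT_VISCOSITY = 1.0e-3  # Pa s, water at ~20 C
DEFAULT_VELOCITY_TRUNCATION = 3
DEFAULT_SHEAR_TRUNCATION = 200
DEFAULT_FLOW_TRUNCATION = 20
MIN_SHEAR_TRUNCATION = 100


def _cosh_ratio(a, b):
    """cosh(a)/cosh(b) for |a| <= b, overflow-safe at large arguments."""
    a = np.abs(np.asarray(a, dtype=float))
    b = np.asarray(b, dtype=float)
    return np.exp(a - b) * (1.0 + np.exp(-2.0 * a)) / (1.0 + np.exp(-2.0 * b))


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular duct cross-section.

    ``y`` runs across the width from one side wall (y = 0) to the other
    (y = w); ``z`` runs from the glass bottom (z = 0) to the top (z = h);
    ``x`` is the flow direction.  ``length`` is informational.
    """

    height: float  # m
    width: float  # m
    length: float = 30e-3  # m

    def __post_init__(self):
        if not (self.height > 0 and self.width > 0):
            raise InvalidInputError(
                f"channel dimensions must be positive, got h={self.height}, w={self.width}"
            )

    @classmethod
    def from_um(cls, height_um: float, width_um: float, length_mm: float = 30.0):
        return cls(height_um * 1e-6, width_um * 1e-6, length_mm * 1e-3)

    def p(self, n):
        """Height-wise wavenumbers p_n = (2n+1) pi / h."""
        return (2 * np.asarray(n) + 1) * np.pi / self.height

    def q(self, n):
        """Width-wise wavenumbers q_n = (2n+1) pi / w."""
        return (2 * np.asarray(n) + 1) * np.pi / self.width

    def contains(self, y, z) -> bool:
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        return bool(
            np.all((y >= 0) & (y <= self.width) & (z >= 0) & (z <= self.height))
        )


def velocity_scale(geometry: ChannelGeometry, pressure_gradient: float,
                   viscosity: float = DEFAULT_VISCOSITY) -> float:
    """v1 = (G / 8 eta) w^2 h^2 / (w^2 + h^2), the series prefactor.

    This is the formula-defined scale; it approximates, but does not equal,
    the mid-channel velocity.
    """
    w, h = geometry.width, geometry.height
    return pressure_gradient / (8.0 * viscosity) * (w * h) ** 2 / (w**2 + h**2)


def _q_series_factor(geometry: ChannelGeometry, truncation: int) -> float:
    """The braced factor of the Q series; terms decay as 1/(2n+1)^5."""
    if truncation < 2:
        raise InvalidInputError("flow-rate series truncation must be >= 2")
    w, h = geometry.width, geometry.height
    n = np.arange(truncation + 1)
    c5 = (2.0 / ((2 * n + 1) * np.pi)) ** 5
    terms = c5 * (
        (h / w) * np.tanh(geometry.p(n) * w / 2.0)
        + (w / h) * np.tanh(geometry.q(n) * h / 2.0)
    )
    return 1.0 / 3.0 - terms.sum()


def flow_rate(geometry: ChannelGeometry, pressure_gradient: float,
              viscosity: float = DEFAULT_VISCOSITY,
              truncation: int = DEFAULT_FLOW_TRUNCATION) -> float:
    """Volumetric rate Q (m^3/s) for a pressure gradient G = -dp/dx (Pa/m)."""
    v1 = velocity_scale(geometry, pressure_gradient, viscosity)
    return 4.0 * geometry.width * geometry.height * v1 * _q_series_factor(
        geometry, truncation
    )


def pressure_gradient_for_flow(geometry: ChannelGeometry, flow_rate_m3s: float,
                               viscosity: float = DEFAULT_VISCOSITY,
                               truncation: int = DEFAULT_FLOW_TRUNCATION) -> float:
    """Invert the (linear) Q series: G such that flow_rate(G) == Q."""
    if flow_rate_m3s <= 0:
        raise InvalidInputError("flow rate must be positive")
    if viscosity <= 0:
        raise InvalidInputError("viscosity must be positive")
    q_per_g = flow_rate(geometry, 1.0, viscosity, truncation)
    return flow_rate_m3s / q_per_g


@dataclass(frozen=True)
class FlowDrive:
    """Imposed flow and derived drive quantities.

    The volumetric rate Q is the canonical input (the pump imposes it); the
    pressure gradient G = -dp/dx and the velocity scale v1 are derived and
    co-signed with Q.
    """

    flow_rate: float  # m^3/s
    viscosity: float  # Pa s
    pressure_gradient: float  # Pa/m
    velocity_scale: float  # m/s

    @classmethod
    def from_flow_rate(cls, geometry: ChannelGeometry, flow_rate_m3s: float,
                       viscosity: float = DEFAULT_VISCOSITY,
                       truncation: int = DEFAULT_FLOW_TRUNCATION) -> "FlowDrive":
        g = pressure_gradient_for_flow(geometry, flow_rate_m3s, viscosity, truncation)
        return cls(flow_rate_m3s, viscosity, g, velocity_scale(geometry, g, viscosity))

    @classmethod
    def from_ml_per_h(cls, geometry: ChannelGeometry, flow_rate_ml_h: float,
                      viscosity: float = DEFAULT_VISCOSITY,
                      truncation: int = DEFAULT_FLOW_TRUNCATION) -> "FlowDrive":
        return cls.from_flow_rate(geometry, flow_rate_ml_h * ML_PER_H,
                                  viscosity, truncation)


def velocity_at(geometry: ChannelGeometry, drive: FlowDrive, y, z,
                truncation: int = DEFAULT_VELOCITY_TRUNCATION):
    """Axial velocity v(y, z) in m/s from the truncated series.

    ``truncation`` is the index of the last retained term (n = 0..truncation);
    the instrument-matching default keeps terms through n = 3.
    Accepts scalars or broadcastable arrays for ``y`` and ``z``.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not geometry.contains(y, z):
        raise DomainError("(y, z) outside the channel cross-section")
    w, h = geometry.width, geometry.height
    yb, zb = np.broadcast_arrays(y, z)
    n = np.arange(truncation + 1).reshape((-1,) + (1,) * yb.ndim)
    p = (2 * n + 1) * np.pi / h
    q = (2 * n + 1) * np.pi / w
    c3 = (2.0 / ((2 * n + 1) * np.pi)) ** 3
    # distances to the mid-planes; cosh and cos are even, so evaluating on
    # |.| makes mirror symmetry v(y,z) = v(w-y,z) = v(y,h-z) bit-exact
    dy = np.abs(yb - w / 2.0)[None, ...]
    dz = np.abs(zb - h / 2.0)[None, ...]
    t1 = _cosh_ratio(p * dy, p * w / 2.0) * np.cos(p * dz)
    t2 = _cosh_ratio(q * dz, q * h / 2.0) * np.cos(q * dy)
    series = ((-1.0) ** n * c3 * (t1 + t2)).sum(axis=0)
    # (y/w)(1 - y/w) + (z/h)(1 - z/h), written in centered (mirror-even) form
    poly = 0.5 - (dy[0] / w) ** 2 - (dz[0] / h) ** 2
    out = 4.0 * drive.velocity_scale * (poly - series)
    return out if yb.shape else float(out)


def bottom_shear_at(geometry: ChannelGeometry, drive: FlowDrive, y,
                    truncation: int = DEFAULT_SHEAR_TRUNCATION):
    """Bottom-wall shear stress sigma(y) = eta dv/dz at z = 0, in Pa.

    The differentiated series decays only as 1/(2n+1)^2, so truncation below
    ``MIN_SHEAR_TRUNCATION`` triggers an accuracy warning (n = 3 is ~4% off
    on a square duct).
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > geometry.width)):
        raise DomainError("y outside [0, w]")
    if truncation < MIN_SHEAR_TRUNCATION:
        warnings.warn(
            f"shear series truncated at n={truncation} < {MIN_SHEAR_TRUNCATION}; "
            "the differentiated series converges as 1/(2n+1)^2 and accuracy "
            "degrades to the percent level",
            stacklevel=2,
        )
    w, h = geometry.width, geometry.height
    n = np.arange(truncation + 1).reshape((-1,) + (1,) * y.ndim)
    p = (2 * n + 1) * np.pi / h
    q = (2 * n + 1) * np.pi / w
    c3 = (2.0 / ((2 * n + 1) * np.pi)) ** 3
    dy = np.abs(y - w / 2.0)[None, ...]  # even in (y - w/2): sigma(y) = sigma(w-y)
    terms = c3 * (
        p * _cosh_ratio(p * dy, p * w / 2.0)
        - (-1.0) ** n * q * np.tanh(q * h / 2.0) * np.cos(q * dy)
    )
    bracket = 1.0 / h - terms.sum(axis=0)
    out = 4.0 * drive.viscosity * drive.velocity_scale * bracket
    return out if y.shape else float(out)


def side_shear_at(geometry: ChannelGeometry, drive: FlowDrive, z,
                  truncation: int = DEFAULT_SHEAR_TRUNCATION):
    """Side-wall shear stress eta dv/dy at y = 0 as a function of z, in Pa.

    Obtained from the bottom-wall formula by the (y, w) <-> (z, h) symmetry
    of the field; the drive quantities are themselves symmetric under the
    swap.  Used for the wall-drag / pressure-force balance.
    """
    swapped = ChannelGeometry(geometry.width, geometry.height, geometry.length)
    return bottom_shear_at(swapped, drive, z, truncation)


@dataclass(frozen=True)
class ShearProfile:
    """Bottom shear sigma(y) sampled on a uniform transverse grid."""

    y: np.ndarray  # m
    sigma: np.ndarray  # Pa

    @property
    def max_shear(self) -> float:
        return float(self.sigma.max())

    @property
    def y_at_max(self) -> float:
        return float(self.y[int(np.argmax(self.sigma))])

    def mean_over(self, y_lo: float, y_hi: float) -> float:
        """Arithmetic mean of sigma over [y_lo, y_hi] (grid-restricted)."""
        mask = (self.y >= y_lo) & (self.y <= y_hi)
        if not mask.any():
            raise DomainError("interval contains no grid point")
        return float(self.sigma[mask].mean())


def bottom_shear_profile(geometry: ChannelGeometry, drive: FlowDrive,
                         step: float = 5e-6,
                         truncation: int = DEFAULT_SHEAR_TRUNCATION) -> ShearProfile:
    """sigma(y) on a uniform grid over [0, w] with spacing <= ``step``."""
    if step <= 0:
        raise InvalidInputError("sampling step must be positive")
    n_pts = int(np.ceil(geometry.width / step)) + 1
    y = np.linspace(0.0, geometry.width, n_pts)
    return ShearProfile(y=y, sigma=np.asarray(
        bottom_shear_at(geometry, drive, y, truncation)))


@dataclass(frozen=True)
class ROILayout:
    """Adjacent analysis strips marching inward from a side wall.

    ROI ``i`` (1-based) covers [(i-1) roi_width, i roi_width] from the wall
    plus a fixed edge offset; the defaults give ten 40-um strips ending
    400 um from the edge.
    """

    roi_width: float = 40e-6  # m
    n_rois: int = 10
    edge_offset: float = 0.0  # m

    def __post_init__(self):
        if self.roi_width <= 0 or self.n_rois < 1 or self.edge_offset < 0:
            raise InvalidInputError("invalid ROI layout")

    def interval(self, roi_index: int) -> tuple[float, float]:
        if not 1 <= roi_index <= self.n_rois:
            raise InvalidInputError(
                f"roi_index {roi_index} outside 1..{self.n_rois}")
        lo = self.edge_offset + (roi_index - 1) * self.roi_width
        return lo, lo + self.roi_width

    def right_boundary_um(self, roi_index: int) -> float:
        """Distance (um) of the ROI's inner boundary from the channel edge."""
        return self.interval(roi_index)[1] * 1e6


def roi_mean_bottom_shear(geometry: ChannelGeometry, drive: FlowDrive,
                          layout: ROILayout, roi_index: int,
                          truncation: int = DEFAULT_SHEAR_TRUNCATION,
                          grid_step: float = 1e-6) -> float:
    """Arithmetic mean of sigma(y) over one ROI on a <= 1 um grid, in Pa."""
    lo, hi = layout.interval(roi_index)
    if hi > geometry.width:
        raise DomainError("ROI extends beyond the channel width")
    n_pts = int(np.ceil((hi - lo) / grid_step)) + 1
    y = np.linspace(lo, hi, n_pts)
    return float(np.mean(bottom_shear_at(geometry, drive, y, truncation)))


def effective_geometry(geometry: ChannelGeometry, *,
                       biofilm_thickness: float | None = None,
                       front_advance: float | None = None) -> ChannelGeometry:
    """Cross-section left open once biofilm occupies part of the channel.

    Uniform-growth mode: a bottom layer of ``biofilm_thickness`` reduces the
    height.  Advancing-front mode: fronts progressing ``front_advance`` from
    each side wall reduce the width by twice that amount.  The imposed flow
    rate is unchanged; rebuild the drive on the returned geometry.
    """
    if (biofilm_thickness is None) == (front_advance is None):
        raise InvalidInputError(
            "specify exactly one of biofilm_thickness or front_advance")
    if biofilm_thickness is not None:
        if biofilm_thickness < 0:
            raise InvalidInputError("biofilm thickness must be >= 0")
        h_eff = geometry.height - biofilm_thickness
        if h_eff <= 0:
            raise OcclusionError("biofilm layer occludes the channel")
        return replace(geometry, height=h_eff)
    if front_advance < 0:
        raise InvalidInputError("front advance must be >= 0")
    w_eff = geometry.width - 2.0 * front_advance
    if w_eff <= 0:
        raise OcclusionError("advancing fronts occlude the channel")
    return replace(geometry, width=w_eff)


def shear_force(sigma: float, area: float) -> float:
    """Tangential drag F = sigma * A (N) on a footprint of area A.

    At the ~10 mPa colonization threshold a 1 um^2 bacterial footprint
    feels 1e-14 N, i.e. 0.01 pN.
    """
    return sigma * area
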