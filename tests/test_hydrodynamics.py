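"""Rectangular-duct flow: series solution, shear maps, effective geometry."""

import numpy as np
import pytest
from scipy.integrate import simpson

from milliflow.errors import DomainError, InvalidInputError, OcclusionError
from milliflow.hydrodynamics import (
    ML_PER_H,
    ChannelGeometry,
    FlowDrive,
    ROILayout,
    bottom_shear_at,
    bottom_shear_profile,
    effective_geometry,
    flow_rate,
    pressure_gradient_for_flow,
    roi_mean_bottom_shear,
    shear_force,
    side_shear_at,
    velocity_at,
    velocity_scale,
)

# classic tabulated friction coefficient: Q = 0.035144 G a^4 / eta for a
# square duct of side a (independent closed-form oracle)
SQUARE_DUCT_Q_COEFF = 0.035144
# high-order series oracle for the square-duct maximum velocity
SQUARE_DUCT_VMAX_COEFF = 0.0737


class TestFlowRateSeries:
    def test_square_duct_friction_coefficient(self, square_channel):
        g = 1.0
        q = flow_rate(square_channel, g, 1e-3, truncation=50)
        coeff = q * 1e-3 / (g * square_channel.height**4)
        assert coeff == pytest.approx(SQUARE_DUCT_Q_COEFF, rel=1e-4)

    def test_pressure_gradient_square_duct_oracle(self, square_channel):
        g = pressure_gradient_for_flow(square_channel, ML_PER_H, 1e-3)
        g_oracle = ML_PER_H * 1e-3 / (SQUARE_DUCT_Q_COEFF * square_channel.height**4)
        assert g == pytest.approx(g_oracle, rel=1e-4)
        assert g == pytest.approx(7.90, rel=1e-2)

    def test_linearity_in_flow_rate(self, square_channel):
        g1 = pressure_gradient_for_flow(square_channel, ML_PER_H, 1e-3)
        g2 = pressure_gradient_for_flow(square_channel, 2 * ML_PER_H, 1e-3)
        assert g2 == pytest.approx(2 * g1, rel=1e-14)

    def test_round_trip_identity(self, square_channel, shallow_channel):
        for geom in (square_channel, shallow_channel):
            g = pressure_gradient_for_flow(geom, ML_PER_H, 1e-3)
            assert flow_rate(geom, g, 1e-3) == pytest.approx(ML_PER_H, rel=1e-12)

    def test_zero_gradient_zero_flow(self, square_channel):
        assert flow_rate(square_channel, 0.0) == 0.0

    def test_invalid_inputs(self, square_channel):
        with pytest.raises(InvalidInputError):
            pressure_gradient_for_flow(square_channel, -1e-9)
        with pytest.raises(InvalidInputError):
            ChannelGeometry(-1e-3, 1e-3)
        with pytest.raises(InvalidInputError):
            flow_rate(square_channel, 1.0, truncation=1)


class TestVelocityField:
    def test_no_slip_walls(self, square_channel, square_drive):
        g, d = square_channel, square_drive
        vmax = velocity_at(g, d, g.width / 2, g.height / 2, truncation=10)
        pts = np.linspace(0, g.width, 7)
        for v in (velocity_at(g, d, 0.0, pts * g.height / g.width, 10),
                  velocity_at(g, d, g.width, pts * g.height / g.width, 10),
                  velocity_at(g, d, pts, 0.0, 10),
                  velocity_at(g, d, pts, g.height, 10)):
            assert np.all(np.abs(v) <= 0.005 * vmax)

    def test_square_duct_centre_velocity_oracle(self, square_channel, square_drive):
        v = velocity_at(square_channel, square_drive,
                        square_channel.width / 2, square_channel.height / 2,
                        truncation=50)
        coeff = v * square_drive.viscosity / (
            square_drive.pressure_gradient * square_channel.height**2)
        assert coeff == pytest.approx(SQUARE_DUCT_VMAX_COEFF, abs=5e-4)

    def test_mirror_symmetry_bit_identical(self, dyadic_channel):
        g = dyadic_channel
        d = FlowDrive.from_ml_per_h(g, 1.0)
        k = np.array([1, 2, 3, 5])  # eighths of the side: exact mirrors
        y, z = g.width * k / 8, g.height * k[::-1] / 8
        v = velocity_at(g, d, y, z)
        assert np.array_equal(v, velocity_at(g, d, g.width - y, z))
        assert np.array_equal(v, velocity_at(g, d, y, g.height - z))

    def test_mass_conservation_quadrature(self, square_channel, square_drive):
        g, d = square_channel, square_drive
        y = np.linspace(0, g.width, 301)
        z = np.linspace(0, g.height, 301)
        v = velocity_at(g, d, y[:, None], z[None, :], truncation=10)
        q_num = simpson(simpson(v, x=z, axis=1), x=y)
        assert q_num == pytest.approx(d.flow_rate, rel=5e-3)

    def test_out_of_domain_raises(self, square_channel, square_drive):
        with pytest.raises(DomainError):
            velocity_at(square_channel, square_drive, -1e-6, 0.0)
        with pytest.raises(DomainError):
            velocity_at(square_channel, square_drive, 0.0, 2e-3)


class TestBottomShear:
    def test_printed_maxima(self, square_channel, square_drive,
                            shallow_channel, shallow_drive):
        """Mid-width bottom shear for the bare and biofilm-reshaped ducts."""
        s1 = bottom_shear_at(square_channel, square_drive,
                             square_channel.width / 2) * 1e3
        assert s1 == pytest.approx(2.67, rel=0.02)
        s2 = bottom_shear_at(shallow_channel, shallow_drive,
                             shallow_channel.width / 2) * 1e3
        assert s2 == pytest.approx(31.5, rel=0.02)

    def test_finite_difference_oracle(self, square_channel, square_drive):
        """Analytic z-derivative vs a second-order one-sided stencil at z=0."""
        g, d = square_channel, square_drive
        y = np.linspace(0.01 * g.width, 0.99 * g.width, 50)
        eps = g.height * 1e-4
        fd = d.viscosity * (4 * velocity_at(g, d, y, eps, 400)
                            - velocity_at(g, d, y, 2 * eps, 400)) / (2 * eps)
        analytic = bottom_shear_at(g, d, y, truncation=400)
        assert np.max(np.abs(fd / analytic - 1)) < 2e-3

    def test_wall_zeros_symmetry_positivity(self, shallow_channel, shallow_drive):
        g, d = shallow_channel, shallow_drive
        prof = bottom_shear_profile(g, d)
        assert prof.sigma[0] == pytest.approx(0.0, abs=1e-3 * prof.max_shear)
        assert prof.sigma[-1] == pytest.approx(0.0, abs=1e-3 * prof.max_shear)
        np.testing.assert_allclose(prof.sigma, prof.sigma[::-1], rtol=1e-9)
        assert np.all(prof.sigma >= -1e-12)
        assert prof.y_at_max == pytest.approx(g.width / 2, abs=5e-6)

    def test_low_truncation_warns(self, square_channel, square_drive):
        with pytest.warns(UserWarning, match="truncated"):
            bottom_shear_at(square_channel, square_drive,
                            square_channel.width / 2, truncation=3)

    def test_force_balance(self, square_channel, square_drive,
                           shallow_channel, shallow_drive):
        """Wall-integrated drag equals the pressure force G*w*h per unit length."""
        for g, d in ((square_channel, square_drive),
                     (shallow_channel, shallow_drive)):
            y = np.linspace(0, g.width, 2001)
            z = np.linspace(0, g.height, 2001)
            drag = (2 * np.trapezoid(bottom_shear_at(g, d, y, 400), y)
                    + 2 * np.trapezoid(side_shear_at(g, d, z, 400), z))
            assert drag == pytest.approx(d.pressure_gradient * g.width * g.height,
                                         rel=0.01)

    def test_parallel_plate_limit(self):
        """Wide-channel maximum shear approaches 6 eta Q / (w h^2)."""
        g = ChannelGeometry.from_um(40, 1000)  # w/h = 25
        d = FlowDrive.from_ml_per_h(g, 1.0)
        plate = 6 * d.viscosity * d.flow_rate / (g.width * g.height**2)
        assert bottom_shear_at(g, d, g.width / 2) == pytest.approx(plate, rel=0.03)

    def test_linear_scaling_in_q_and_eta(self, square_channel):
        d1 = FlowDrive.from_ml_per_h(square_channel, 1.0, 1e-3)
        d2 = FlowDrive.from_ml_per_h(square_channel, 3.0, 1e-3)
        d3 = FlowDrive.from_ml_per_h(square_channel, 1.0, 2e-3)
        y = square_channel.width * 0.3
        s1 = bottom_shear_at(square_channel, d1, y)
        assert bottom_shear_at(square_channel, d2, y) == pytest.approx(3 * s1, rel=1e-12)
        assert bottom_shear_at(square_channel, d3, y) == pytest.approx(2 * s1, rel=1e-12)

    def test_five_channel_ordering(self):
        """Across the five-channel set at 1 mL/h, the 250 um duct is harshest."""
        maxima = {}
        for h_um in (250, 350, 500, 750, 1000):
            g = ChannelGeometry.from_um(h_um, 1000)
            d = FlowDrive.from_ml_per_h(g, 1.0)
            maxima[h_um] = bottom_shear_at(g, d, g.width / 2)
        assert max(maxima, key=maxima.get) == 250
        assert sorted(maxima, key=maxima.get) == [1000, 750, 500, 350, 250]


class TestROIMeans:
    def test_mean_over_full_width_is_total_drag(self, square_channel, square_drive):
        lay = ROILayout(roi_width=square_channel.width, n_rois=1)
        mean = roi_mean_bottom_shear(square_channel, square_drive, lay, 1)
        y = np.linspace(0, square_channel.width, 1001)
        drag_per_width = np.trapezoid(
            bottom_shear_at(square_channel, square_drive, y), y) / square_channel.width
        assert mean == pytest.approx(drag_per_width, rel=1e-3)

    def test_means_increase_toward_centre(self, shallow_channel, shallow_drive, layout):
        means = [roi_mean_bottom_shear(shallow_channel, shallow_drive, layout, i)
                 for i in range(1, layout.n_rois + 1)]
        assert np.all(np.diff(means) > 0)
        # edge-ROI mean sits below the shear at its own inner boundary
        boundary = bottom_shear_at(shallow_channel, shallow_drive, layout.interval(1)[1])
        assert means[0] < boundary

    def test_layout_geometry(self, layout):
        assert layout.interval(1)[0] == 0.0
        assert layout.interval(10)[1] == pytest.approx(400e-6)
        with pytest.raises(InvalidInputError):
            layout.interval(11)

    def test_roi_beyond_width_raises(self, shallow_channel, shallow_drive):
        lay = ROILayout(roi_width=300e-6, n_rois=4)
        with pytest.raises(DomainError):
            roi_mean_bottom_shear(shallow_channel, shallow_drive, lay, 4)


class TestEffectiveGeometry:
    def test_uniform_layer_printed_value(self, square_channel):
        g_eff = effective_geometry(square_channel, biofilm_thickness=70e-6)
        assert g_eff.height == pytest.approx(930e-6)
        d = FlowDrive.from_ml_per_h(g_eff, 1.0)
        s = bottom_shear_at(g_eff, d, g_eff.width / 2) * 1e3
        assert s == pytest.approx(3.02, rel=0.02)

    def test_advancing_front_printed_value(self, shallow_channel):
        g_eff = effective_geometry(shallow_channel, front_advance=250e-6)
        assert g_eff.width == pytest.approx(0.5e-3)
        d = FlowDrive.from_ml_per_h(g_eff, 1.0)
        s = bottom_shear_at(g_eff, d, g_eff.width / 2) * 1e3
        assert s == pytest.approx(72.3, rel=0.02)

    def test_identity_and_occlusion(self, square_channel):
        same = effective_geometry(square_channel, biofilm_thickness=0.0)
        assert same.height == square_channel.height
        with pytest.raises(OcclusionError):
            effective_geometry(square_channel, biofilm_thickness=2e-3)
        with pytest.raises(OcclusionError):
            effective_geometry(square_channel, front_advance=0.6e-3)
        with pytest.raises(InvalidInputError):
            effective_geometry(square_channel)


def test_velocity_scale_definition(square_channel):
    g = 10.0
    v1 = velocity_scale(square_channel, g, 1e-3)
    w, h = square_channel.width, square_channel.height
    assert v1 == g / (8 * 1e-3) * w**2 * h**2 / (w**2 + h**2)


def test_shear_force_bacterium_scale():
    """A 1 um^2 footprint at the ~10 mPa threshold feels 0.01 pN."""
    f = shear_force(10e-3, 1e-12)
    assert f == pytest.approx(1e-14)
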