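"""Pressure-loss coefficient, dome-averaged WSS and profile comparison."""

import numpy as np
import pytest

from hemolattice.postprocess import (
    CenterlineProfile,
    PlaneProbe,
    dome_average_wss,
    plane_probe,
    pressure_loss_coefficient,
    relative_difference,
)


def probe(p, u):
    return PlaneProbe(
        center=np.zeros(3), normal=np.array([0, 0, 1.0]), radius=1e-3,
        p_mean=p, u_mean=u, n_samples=50,
    )


class TestPLc:
    def test_no_loss_is_zero(self):
        assert pressure_loss_coefficient(
            probe(1000.0, 0.4), probe(1000.0, 0.4), 1000.0
        ) == pytest.approx(0.0)

    def test_unit_normalization(self):
        rho, u = 1000.0, 0.4
        dyn = 0.5 * rho * u**2
        assert pressure_loss_coefficient(
            probe(2000.0, u), probe(2000.0 - dyn, u), rho
        ) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        # rho=1000, u_in=0.5, P_in=2000, u_out=0.25, P_out=1800 -> 2.35
        val = pressure_loss_coefficient(
            probe(2000.0, 0.5), probe(1800.0, 0.25), 1000.0
        )
        assert val == pytest.approx(2.35, rel=1e-12)

    def test_gauge_invariance(self):
        a = pressure_loss_coefficient(
            probe(2000.0, 0.5), probe(1800.0, 0.25), 1000.0
        )
        b = pressure_loss_coefficient(
            probe(2000.0 + 5e4, 0.5), probe(1800.0 + 5e4, 0.25), 1000.0
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_lossless_bernoulli_contraction(self):
        """Hand-constructed inviscid contraction has PLc = 0 exactly."""
        rho = 1000.0
        u_in, u_out = 0.3, 0.9
        p_in = 1500.0
        p_out = p_in + 0.5 * rho * (u_in**2 - u_out**2)
        assert pressure_loss_coefficient(
            probe(p_in, u_in), probe(p_out, u_out), rho
        ) == pytest.approx(0.0, abs=1e-12)

    def test_zero_inlet_velocity_rejected(self):
        with pytest.raises(ValueError):
            pressure_loss_coefficient(probe(0.0, 0.0), probe(0.0, 0.0), 1000.0)


class TestPlaneProbe:
    def test_samples_and_means(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1e-3, 1e-3, (500, 3))
        pts[:, 2] *= 0.05
        p = np.full(len(pts), 42.0)
        u = np.tile([0.0, 0.0, 0.3], (len(pts), 1))
        pr = plane_probe(
            pts, p, u, np.zeros(3), [0, 0, 1.0], radius=1e-3,
            thickness=5e-5,
        )
        assert pr.p_mean == pytest.approx(42.0)
        assert pr.u_mean == pytest.approx(0.3)
        assert pr.n_samples >= 10

    def test_vector_vs_magnitude_mean(self):
        pts = np.zeros((20, 3))
        pts[:, 0] = np.linspace(-1e-4, 1e-4, 20)
        p = np.zeros(20)
        u = np.zeros((20, 3))
        u[:10, 2] = 0.2
        u[10:, 2] = -0.2
        kw = dict(center=np.zeros(3), normal=[0, 0, 1.0], radius=1e-3,
                  thickness=1e-3)
        vec = plane_probe(pts, p, u, mean_velocity="vector", **kw)
        mag = plane_probe(pts, p, u, mean_velocity="magnitude", **kw)
        assert vec.u_mean == pytest.approx(0.0, abs=1e-12)
        assert mag.u_mean == pytest.approx(0.2)

    def test_too_few_samples_rejected(self):
        pts = np.zeros((5, 3))
        with pytest.raises(ValueError, match="10"):
            plane_probe(
                pts, np.zeros(5), np.zeros((5, 3)), np.zeros(3),
                [0, 0, 1.0], radius=1e-3, thickness=1e-4,
            )


class TestDomeAverage:
    def test_uniform_field_returns_the_value(self):
        tids = np.array([0, 1, 2, 3])
        tags = np.array(["dome", "dome", "dome", "wall"])
        areas = np.array([1.0, 2.0, 3.0, 4.0])
        wss = np.array([0.7, 0.7, 0.7, 9.9])
        assert dome_average_wss(wss, tids, tags, areas) == pytest.approx(0.7)

    def test_partition_additivity(self):
        """Splitting the dome into two tags reproduces the single-tag mean."""
        rng = np.random.default_rng(1)
        n = 40
        tids = np.arange(n)
        areas = rng.uniform(0.5, 2.0, n)
        wss = rng.uniform(0.1, 3.0, n)
        whole = dome_average_wss(
            wss, tids, np.array(["dome"] * n), areas
        )
        half = np.array(["dome_a"] * (n // 2) + ["dome_b"] * (n // 2))
        a = dome_average_wss(wss, tids, half, areas, dome_tag="dome_a")
        b = dome_average_wss(wss, tids, half, areas, dome_tag="dome_b")
        wa = areas[: n // 2].sum()
        wb = areas[n // 2:].sum()
        assert (a * wa + b * wb) / (wa + wb) == pytest.approx(whole)

    def test_empty_dome_rejected(self):
        with pytest.raises(ValueError):
            dome_average_wss(
                np.ones(3), np.arange(3), np.array(["wall"] * 3), np.ones(3)
            )


class TestRelativeDifference:
    def test_identical_profiles_are_zero(self):
        s = np.linspace(0, 1, 50)
        a = CenterlineProfile(0, s, np.sin(s) + 2, np.cos(s) + 2)
        d = relative_difference(a, a)
        assert np.allclose(d, 0.0)

    def test_closed_form_arithmetic(self):
        # f_a = 1.02, f_b = 1.0, reference mean forced to 2.0 -> d = 1%
        fa = np.full(10, 1.02)
        fb = np.full(10, 1.0)
        d = np.abs(fa - fb) / 2.0 * 100
        assert np.allclose(d, 1.0)
        # and through the implementation with its own mean (=1.0): 2%
        assert np.allclose(relative_difference(fa, fb), 2.0)

    def test_monte_carlo_perturbation_oracle(self):
        """Random perturbation of amplitude eps on a flat profile: the mean
        relative difference approaches (E|eps| / m) * 100."""
        rng = np.random.default_rng(7)
        m = 2.5
        eps = 0.05
        fb = np.full(20000, m)
        noise = rng.uniform(-eps, eps, fb.size)
        d = relative_difference(fb + noise, fb)
        expected = (eps / 2) / m * 100  # E|U(-eps, eps)| = eps/2
        assert d.mean() == pytest.approx(expected, rel=0.02)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(np.ones(4), np.zeros(4))

    def test_mismatched_arclength_rejected(self):
        s = np.linspace(0, 1, 10)
        a = CenterlineProfile(0, s, np.ones(10), np.ones(10))
        b = CenterlineProfile(0, s + 0.1, np.ones(10), np.ones(10))
        with pytest.raises(ValueError):
            relative_difference(a, b)
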