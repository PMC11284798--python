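"""Geometric kernel: harmonic fitting, curvature, arc discretization, queries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from membuckle.surface import (
    SurfaceFit,
    discretize,
    fit_surface,
    local_normal,
    nearest_arc_point,
    periodic_delta,
)

L = 24.0


def sample_curve(fit, n=200, x_max=None):
    x = np.linspace(0.0, x_max or fit.L_x, n, endpoint=False)
    return np.column_stack([x, fit.z(x)])


class TestFit:
    def test_exact_single_harmonic(self):
        x = np.linspace(0, L, 200, endpoint=False)
        pts = np.column_stack([x, 5.0 + 1.5 * np.sin(2 * np.pi * x / L)])
        fit = fit_surface(pts, L, 6)
        assert fit.A0 == pytest.approx(5.0, abs=1e-10)
        assert fit.amplitudes[0] == pytest.approx(1.5, abs=1e-10)
        assert np.all(fit.amplitudes[1:] < 1e-8)
        assert fit.residual_rms < 1e-8

    def test_flat_line(self):
        x = np.linspace(0, L, 50)
        fit = fit_surface(np.column_stack([x, np.full_like(x, 3.0)]), L, 6)
        assert fit.A0 == pytest.approx(3.0, abs=1e-12)
        assert np.all(fit.amplitudes < 1e-10)

    def test_exact_three_harmonics_with_phases(self):
        truth = SurfaceFit(L_x=L, A0=6.0, amplitudes=np.array([2.0, 0.7, 0.25]),
                           phases=np.array([3.1, 1.2, 0.4]))
        fit = fit_surface(sample_curve(truth, 200), L, 3)
        assert np.allclose(fit.amplitudes, truth.amplitudes, atol=1e-8)
        assert np.allclose(fit.phases, truth.phases, atol=1e-8)
        assert abs(fit.A0 - truth.A0) < 1e-8

    def test_noisy_amplitudes_within_regression_error(self):
        # linear-regression variance oracle: coefficient sd ~ sigma*sqrt(2/n)
        rng = np.random.default_rng(0)
        truth = SurfaceFit(L_x=L, A0=5.0, amplitudes=np.array([1.5, 0.5, 0.2]),
                           phases=np.zeros(3))
        n, sigma = 400, 0.05
        pts = sample_curve(truth, n)
        pts[:, 1] += rng.normal(0, sigma, n)
        fit = fit_surface(pts, L, 3)
        tol = 4 * sigma * np.sqrt(2.0 / n)
        assert np.all(np.abs(fit.amplitudes - truth.amplitudes) < tol)

    def test_errors(self):
        x = np.linspace(0, L, 50)
        pts = np.column_stack([x, np.sin(x)])
        with pytest.raises(ValueError):
            fit_surface(pts, L, 0)
        with pytest.raises(ValueError):
            fit_surface(np.column_stack([np.full(30, 2.0), np.sin(x[:30])]), L, 6)
        with pytest.raises(ValueError):
            fit_surface(pts[:5], L, 6)  # too few points

    @settings(deadline=None, max_examples=25)
    @given(
        a1=st.floats(0.1, 3.0),
        a2=st.floats(0.0, 1.0),
        p1=st.floats(0.0, 23.9),
        p2=st.floats(0.0, 11.9),
        a0=st.floats(-5, 5),
    )
    def test_fit_idempotent(self, a1, a2, p1, p2, a0):
        """Refitting points sampled from a fit recovers it (modulo gauge)."""
        truth = SurfaceFit(L_x=L, A0=a0, amplitudes=np.array([a1, a2]),
                           phases=np.array([p1, p2]))
        fit = fit_surface(sample_curve(truth, 101), L, 2)
        x = np.linspace(0, L, 57)
        assert np.allclose(fit.z(x), truth.z(x), atol=1e-8)

    def test_residual_decreases_with_harmonics(self):
        truth = SurfaceFit(L_x=L, A0=6.0, amplitudes=np.array([2.0, 0.6, 0.3, 0.15]),
                           phases=np.array([0.3, 2.0, 0.9, 0.1]))
        pts = sample_curve(truth, 300)
        resid = [fit_surface(pts, L, n).residual_rms for n in range(1, 7)]
        assert all(r2 <= r1 + 1e-12 for r1, r2 in zip(resid, resid[1:]))
        assert resid[3] < 1e-10  # 4 harmonics capture the truth exactly


class TestCurvature:
    def test_flat_zero(self):
        fit = SurfaceFit(L_x=L, A0=3.0, amplitudes=np.array([0.0]), phases=np.array([0.0]))
        x = np.linspace(0, L, 20)
        assert np.allclose(fit.curvature(x), 0.0, atol=1e-15)

    def test_sine_crest_symbolic_oracle(self):
        import sympy as sp

        A_v, L_v = 1.5, 24.0
        xs = sp.symbols("x")
        Z = A_v * sp.sin(2 * sp.pi * xs / L_v)
        Ksym = sp.diff(Z, xs, 2) / (1 + sp.diff(Z, xs) ** 2) ** sp.Rational(3, 2)
        expected = float(Ksym.subs(xs, L_v / 4))
        fit = SurfaceFit(L_x=L_v, A0=0.0, amplitudes=np.array([A_v]), phases=np.array([0.0]))
        assert fit.curvature(L_v / 4) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-A_v * (2 * np.pi / L_v) ** 2, abs=1e-12)

    def test_inflection_zero(self):
        fit = SurfaceFit(L_x=L, A0=0.0, amplitudes=np.array([1.5]), phases=np.array([0.0]))
        assert abs(fit.curvature(0.0)) < 1e-12

    def test_crest_negative_trough_positive(self):
        fit = SurfaceFit(L_x=L, A0=5.0, amplitudes=np.array([3.0]), phases=np.array([0.0]))
        assert fit.curvature(L / 4) < 0   # crest (local maximum)
        assert fit.curvature(3 * L / 4) > 0  # trough


class TestNormal:
    def test_flat(self):
        fit = SurfaceFit(L_x=L, A0=3.0, amplitudes=np.array([0.0]), phases=np.array([0.0]))
        assert np.allclose(local_normal(fit, 1.0), [0.0, 1.0])

    def test_crest(self):
        fit = SurfaceFit(L_x=L, A0=0.0, amplitudes=np.array([1.5]), phases=np.array([0.0]))
        assert np.allclose(local_normal(fit, L / 4), [0.0, 1.0], atol=1e-12)

    def test_unit_slope(self):
        # Z' = 1 -> n = (-1, 1)/sqrt(2); build via a steep sine at inflection
        A = L / (2 * np.pi)  # Z'(0) = A * 2 pi / L = 1
        fit = SurfaceFit(L_x=L, A0=0.0, amplitudes=np.array([A]), phases=np.array([0.0]))
        assert np.allclose(local_normal(fit, 0.0), [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_unit_norm_everywhere(self):
        fit = SurfaceFit(L_x=L, A0=1.0, amplitudes=np.array([2.5, 0.3]),
                         phases=np.array([0.2, 3.0]))
        n = local_normal(fit, np.linspace(0, L, 100))
        assert np.allclose(np.linalg.norm(n, axis=-1), 1.0, atol=1e-12)
        assert np.all(n[:, 1] > 0)


class TestDiscretize:
    def test_flat_spacing(self):
        fit = SurfaceFit(L_x=L, A0=3.0, amplitudes=np.array([0.0]), phases=np.array([0.0]))
        disc = discretize(fit, 0.1)
        assert disc.n_points == 240
        assert np.allclose(np.diff(disc.x), 0.1, atol=1e-9)

    def test_total_length_matches_quadrature(self):
        fit = SurfaceFit(L_x=L, A0=0.0, amplitudes=np.array([1.5]), phases=np.array([0.0]))
        quad_len, _ = quad(lambda t: np.sqrt(1 + (1.5 * 2 * np.pi / L * np.cos(2 * np.pi * t / L)) ** 2),
                           0, L, limit=200)
        disc_total = discretize(fit, 0.1).total_length
        assert abs(disc_total - quad_len) / quad_len < 1e-6

    def test_chord_lengths(self):
        fit = SurfaceFit(L_x=L, A0=5.0, amplitudes=np.array([3.0, 0.4]),
                         phases=np.array([0.0, 2.0]))
        disc = discretize(fit, 0.1)
        chords = np.hypot(np.diff(disc.x), np.diff(disc.z))
        assert chords.min() > 0.0999
        assert chords.max() < 0.1001

    def test_delta_s_errors(self):
        fit = SurfaceFit(L_x=L, A0=0.0, amplitudes=np.array([1.0]), phases=np.array([0.0]))
        with pytest.raises(ValueError):
            discretize(fit, 0.0)
        with pytest.raises(ValueError):
            discretize(fit, 30.0)


class TestNearestArcPoint:
    def setup_method(self):
        self.fit = SurfaceFit(L_x=L, A0=5.0, amplitudes=np.array([2.0]),
                              phases=np.array([0.0]))
        self.disc = discretize(self.fit, 0.1)

    def test_on_arc_point(self):
        idx, d = nearest_arc_point(self.disc, (self.disc.x[17], self.disc.z[17]))
        assert idx == 17
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_periodic_wrap(self):
        flat = SurfaceFit(L_x=L, A0=5.0, amplitudes=np.array([0.0]), phases=np.array([0.0]))
        disc = discretize(flat, 0.1)
        p = (L + 0.01, 5.0 + 0.5)  # wraps next to the x = 0.01 region
        idx, d = nearest_arc_point(disc, p)
        assert idx == 0
        assert d == pytest.approx(np.hypot(0.01, 0.5), abs=1e-9)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(-L, 2 * L, 1000), rng.uniform(0, 10, 1000)])
        for px, pz in pts[:200]:
            idx, _ = nearest_arc_point(self.disc, (px, pz))
            dx = periodic_delta(px - self.disc.x, L)
            brute = int(np.argmin(dx**2 + (pz - self.disc.z) ** 2))
            assert idx == brute

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(4)
        px, pz = rng.uniform(0, L, 500), rng.uniform(0, 10, 500)
        vec = self.disc.nearest_index(px, pz)
        scal = [nearest_arc_point(self.disc, (a, b))[0] for a, b in zip(px, pz)]
        assert np.array_equal(vec, scal)


@settings(deadline=None, max_examples=50)
@given(dx=st.floats(-1e4, 1e4), period=st.floats(0.1, 100.0))
def test_periodic_delta_bounds(dx, period):
    d = float(periodic_delta(dx, period))
    assert -period / 2 - 1e-9 <= d < period / 2 + 1e-9
    assert abs((dx - d) / period - round((dx - d) / period)) < 1e-6
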