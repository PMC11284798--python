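"""Thickness, densities and area per lipid against constructions and the
generator's planted laws."""

import numpy as np
import pytest

import membuckle as mb
from membuckle.frames import FrameFits, RoleAtoms, RoleTaggedFrame
from membuckle.geometry import (
    LeafletCurvatureConvention,
    thickness_samples,
)
from membuckle.stats import normalize_to_flat
from membuckle.surface import SurfaceFit, discretize, periodic_delta
from membuckle.synthetic import GeneratorSpec, generate

L = 24.0


def flat_fit(z):
    return SurfaceFit(L_x=L, A0=z, amplitudes=np.array([0.0]), phases=np.array([0.0]))


def sine_fit(A, z0=6.0, phase=0.0):
    return SurfaceFit(L_x=L, A0=z0, amplitudes=np.array([A]), phases=np.array([phase]))


def offset_curve_fit(base, d, n_harmonics=6):
    """Fit of the parallel curve at normal distance d from ``base``."""
    x = np.linspace(0, L, 600, endpoint=False)
    zp = np.asarray(base.dz(x))
    sq = np.sqrt(1 + zp**2)
    px = x - d * zp / sq
    pz = np.asarray(base.z(x)) + d / sq
    return mb.fit_surface(np.column_stack([px, pz]), L, n_harmonics)


def fake_frame_with_fits(upper, lower, mid, n_lipids=4):
    markers = np.column_stack(
        [np.linspace(0, L, n_lipids, endpoint=False), np.full(n_lipids, 3.0),
         np.full(n_lipids, 8.0)]
    )
    fr = RoleTaggedFrame(
        time=0.0, box=(L, 7.5, 12.0), species=np.full(n_lipids, "POPC"),
        markers=markers, roles={"tail_terminal": RoleAtoms(markers, np.arange(n_lipids))},
        leaflet=np.array(["upper", "upper", "lower", "lower"]),
    )
    ff = FrameFits(midplane=mid, upper=upper, lower=lower, time=0.0)
    return fr, ff


class TestConvention:
    def test_leaflet_signs_opposite(self):
        conv = LeafletCurvatureConvention()
        assert conv.sign("upper") == -conv.sign("lower")

    def test_convex_interface_positive(self):
        """At a buckle crest (midplane K < 0) the upper leaflet's interface is
        convex, so its leaflet curvature must be positive."""
        conv = LeafletCurvatureConvention()
        K_mid_at_crest = -0.1
        assert conv.transform(K_mid_at_crest, "upper") > 0
        assert conv.transform(K_mid_at_crest, "lower") < 0

    def test_flip(self):
        conv = LeafletCurvatureConvention()
        assert conv.flipped().transform(0.1, "upper") == -conv.transform(0.1, "upper")


class TestThickness:
    def test_flat_pair(self):
        fr, ff = fake_frame_with_fits(flat_fit(3.9), flat_fit(0.0), flat_fit(1.95))
        res = thickness_samples([fr], [ff])
        assert np.allclose(res.D_PP, 3.9, atol=1e-9)
        assert np.allclose(res.K, 0.0, atol=1e-12)
        assert res.n_excluded == 0

    def test_normal_offset_sine_brute_force_oracle(self):
        """Upper curve = lower offset by d = 3.9 along the normal; recovered
        D_PP within 1% of 3.9 everywhere, against a dense closest-point scan."""
        A = 0.2 / (2 * np.pi / L) ** 2  # crest |K| = 0.2
        lower = sine_fit(A, z0=2.0)
        upper = offset_curve_fit(lower, 3.9)
        mid = offset_curve_fit(lower, 1.95)
        fr, ff = fake_frame_with_fits(upper, lower, mid)
        res = thickness_samples([fr], [ff])
        assert np.all(np.abs(res.D_PP - 3.9) / 3.9 < 0.01)
        # brute force: for a sample of upper-sweep points, scan a dense lower curve
        xq = np.linspace(0, L, 20001)
        zq = np.asarray(lower.z(xq))
        up_disc = ff.disc("upper", 0.1)
        for i in range(0, up_disc.n_points, 37):
            px, pz = up_disc.x[i], up_disc.z[i]
            dx = periodic_delta(px - xq, L)
            brute = np.sqrt(np.min(dx**2 + (pz - zq) ** 2))
            assert brute == pytest.approx(3.9, rel=0.01)

    def test_sweeps_agree_on_symmetric_buckle(self):
        spec = GeneratorSpec(n_lipids=300, n_frames=6, seed=31,
                             include_waters=False, include_chains=False)
        frames, truth = generate(spec)
        fits = mb.fit_frames(frames)
        res = thickness_samples(frames, fits)
        up = res.leaflet == "upper"
        prof_u = mb.stats.bin_and_block(np.abs(res.K[up]), res.D_PP[up], res.time[up],
                                        mb.default_edges(absolute=True))
        prof_l = mb.stats.bin_and_block(np.abs(res.K[~up]), res.D_PP[~up], res.time[~up],
                                        mb.default_edges(absolute=True))
        ok = np.isfinite(prof_u.mean) & np.isfinite(prof_l.mean)
        gap = np.abs(prof_u.mean[ok] - prof_l.mean[ok])
        tol = 3 * np.hypot(prof_u.sem[ok], prof_l.sem[ok]) + 1e-3
        assert np.all(gap < tol)

    def test_thickness_slope_recovery(self):
        """Planted D(K) = D0 + c|K| recovered within 10% for c = +-0.1."""
        for c in (+0.1, -0.1):
            spec = GeneratorSpec(n_lipids=400, n_frames=12, seed=37, d_slope=c,
                                 include_waters=False, include_chains=False)
            frames, _ = generate(spec)
            fits = mb.fit_frames(frames)
            prof = mb.thickness_profile(frames, fits)
            ok = np.isfinite(prof.mean) & (prof.centers < 0.19)
            slope = np.polyfit(prof.centers[ok], prof.mean[ok], 1)[0]
            assert slope == pytest.approx(c, rel=0.1, abs=0.01)


class TestDensities:
    def test_flat_bilayer_counting(self, flat_run):
        """128 lipids per leaflet on a flat 24 x 7.5 box: pooled density is
        exactly 256 / 180 = 1.4222 lipids/nm^2."""
        spec, frames, truth, fits = flat_run
        prof = mb.bilayer_area_density(frames, fits, edges=np.array([0.0, 1.0]))
        expected = 2 * spec.n_lipids / (spec.L_x * spec.L_y)
        assert prof.mean[0] == pytest.approx(expected, rel=1e-6)

    def test_two_terminal_centers_normalization(self):
        """Two terminal centers per lipid give the same density as one."""
        common = dict(n_lipids=200, n_frames=4, seed=41, include_waters=False,
                      include_chains=False)
        f1, _ = generate(GeneratorSpec(n_terminal_centers=1, **common))
        f2, _ = generate(GeneratorSpec(n_terminal_centers=2, **common))
        p1 = mb.bilayer_area_density(f1, mb.fit_frames(f1))
        p2 = mb.bilayer_area_density(f2, mb.fit_frames(f2))
        ok = np.isfinite(p1.mean) & np.isfinite(p2.mean)
        assert np.nansum(p1.mean[ok] * p1.n_samples[ok]) / p1.n_samples[ok].sum() == \
            pytest.approx(np.nansum(p2.mean[ok] * p2.n_samples[ok]) / p2.n_samples[ok].sum(),
                          rel=0.02)

    def test_bilayer_flat_in_abs_K_under_uniform_surface_density(self):
        """Pivotal placement: both leaflets pooled cancel the thin-shell
        modulation, so the bilayer profile is flat in |K| within 2%."""
        spec = GeneratorSpec(n_lipids=2000, n_frames=24, seed=43,
                             include_waters=False, include_chains=False)
        frames, _ = generate(spec)
        prof = normalize_to_flat(mb.bilayer_area_density(frames, mb.fit_frames(frames)))
        ok = np.isfinite(prof.mean) & (prof.centers < 0.19)
        assert np.all(np.abs(prof.mean[ok] - 1.0) < 0.02)

    def test_monolayer_thin_shell_slope(self):
        """Uniform density at pivotal height z_p: the monolayer profile along
        the midplane has normalized slope ~ +z_p in leaflet-signed K."""
        z_p = 1.2
        spec = GeneratorSpec(n_lipids=600, n_frames=16, seed=47, z_p=z_p,
                             include_waters=False, include_chains=False)
        frames, _ = generate(spec)
        prof = normalize_to_flat(mb.monolayer_area_density(frames, mb.fit_frames(frames)))
        ok = np.isfinite(prof.mean) & (np.abs(prof.centers) < 0.19)
        slope = np.polyfit(prof.centers[ok], prof.mean[ok], 1)[0]
        assert abs(slope) == pytest.approx(z_p, rel=0.05)
        assert slope > 0  # denser core under a convex interface

    def test_mirror_symmetry_under_label_swap(self):
        spec = GeneratorSpec(n_lipids=200, n_frames=4, seed=48,
                             include_waters=False, include_chains=False)
        frames, _ = generate(spec)
        fits = mb.fit_frames(frames)
        p1 = mb.monolayer_area_density(frames, fits)
        # swapping leaflet labels together with the sign convention leaves the
        # pooled profile unchanged
        for fr in frames:
            fr.leaflet = np.where(fr.leaflet == "upper", "lower", "upper").astype("U5")
        swapped = [FrameFits(midplane=f.midplane, upper=f.lower, lower=f.upper,
                             time=f.time) for f in fits]
        p2 = mb.monolayer_area_density(frames, swapped,
                                       LeafletCurvatureConvention().flipped())
        for fr in frames:
            fr.leaflet = np.where(fr.leaflet == "upper", "lower", "upper").astype("U5")
        assert np.allclose(p1.mean, p2.mean, equal_nan=True)

    def test_conservation(self):
        spec = GeneratorSpec(n_lipids=150, n_frames=3, seed=49,
                             include_waters=False, include_chains=False)
        frames, _ = generate(spec)
        fits = mb.fit_frames(frames)
        prof = mb.bilayer_area_density(frames, fits, edges=np.array([0.0, 1.0]))
        # total count = density * area summed over all arc-point samples
        dS = frames[0].box[1] * 0.1
        total = prof.block_sums.sum() * dS
        assert total == pytest.approx(2 * spec.n_lipids * spec.n_frames, rel=1e-9)


class TestAreaPerLipid:
    def test_planted_apl_slope(self):
        """Direct APL(K) = apl0 (1 + b K) placement recovered within 5%."""
        spec = GeneratorSpec(n_lipids=600, n_frames=16, seed=51, placement="apl",
                             apl0=0.65, apl_slope=0.5,
                             include_waters=False, include_chains=False)
        frames, _ = generate(spec)
        prof = normalize_to_flat(mb.area_per_lipid(frames, mb.fit_frames(frames)))
        ok = np.isfinite(prof.mean) & (np.abs(prof.centers) < 0.19)
        slope = np.polyfit(prof.centers[ok], prof.mean[ok], 1)[0]
        assert slope == pytest.approx(0.5, rel=0.05)

    def test_apl_and_density_thin_shell_magnitudes(self):
        """Thin-shell geometry: the core-density response scales with the
        pivotal height z_p and the interface-APL response with D/2 - z_p, so
        their relative amplitudes order oppositely as z_p moves."""
        spec = GeneratorSpec(n_lipids=500, n_frames=10, seed=53, z_p=1.2,
                             include_waters=False, include_chains=False)
        frames, _ = generate(spec)
        fits = mb.fit_frames(frames)
        apl = normalize_to_flat(mb.area_per_lipid(frames, fits))
        rho = normalize_to_flat(mb.monolayer_area_density(frames, fits))
        ok = np.isfinite(apl.mean) & np.isfinite(rho.mean) & (np.abs(apl.centers) < 0.19)
        s_apl = np.polyfit(apl.centers[ok], apl.mean[ok], 1)[0]
        s_rho = np.polyfit(rho.centers[ok], rho.mean[ok], 1)[0]
        assert s_apl > 0 and s_rho > 0
        # both increase with K here (z_p above the terminal plane but below
        # the interface): the *relative* responses differ as z_p vs D/2 - z_p
        assert s_rho == pytest.approx(1.2, rel=0.1)
        assert s_apl == pytest.approx(3.9 / 2 - 1.2, rel=0.15)

    def test_refinement_delta_s(self):
        """Doubling the arc spacing changes the overall APL by < 1% and its
        fitted curvature response by < 5% (per-bin values carry bin-level
        sampling noise; the aggregate is the discretization-sensitive part)."""
        spec = GeneratorSpec(n_lipids=500, n_frames=16, seed=55,
                             include_waters=False, include_chains=False)
        frames, _ = generate(spec)
        fits = mb.fit_frames(frames)
        a = mb.area_per_lipid(frames, fits, delta_s=0.1)
        b = mb.area_per_lipid(frames, fits, delta_s=0.2)
        ok = np.isfinite(a.mean) & np.isfinite(b.mean) & (np.abs(a.centers) < 0.19)
        mean_a = np.average(a.mean[ok], weights=a.n_samples[ok])
        mean_b = np.average(b.mean[ok], weights=b.n_samples[ok])
        assert mean_a == pytest.approx(mean_b, rel=0.01)
        sa = np.polyfit(a.centers[ok], a.mean[ok], 1)[0]
        sb = np.polyfit(b.centers[ok], b.mean[ok], 1)[0]
        assert sa == pytest.approx(sb, rel=0.05)
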