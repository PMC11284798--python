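"""Curvature-resolved thickness, area densities and interface area per lipid.

All observables are assigned to local curvature through the fitted surfaces:

* *thickness* ``D_PP`` -- for each point of one leaflet's arc discretization,
  the distance to the closest point of the opposing leaflet curve, assigned to
  the midplane curvature at the arc point nearest to that segment;
* *bilayer area density* -- terminal tail centers of both leaflets binned to
  midplane arc points, per bin area ``dS = L_y * ds``, against |K|;
* *monolayer area density* -- the same per leaflet, against leaflet-signed K;
* *area per lipid* -- phosphorus markers binned to their own leaflet's arc
  points, ``APL = dS / (mean markers per bin)``, against leaflet-signed K.

The sign convention maps the signed midplane curvature to a per-leaflet
curvature that is positive where the lipid-water interface is convex: the
upper leaflet takes ``-K_mid`` (a crest has ``K_mid < 0`` but bulges outward),
the lower leaflet ``+K_mid``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FrameFits, RoleTaggedFrame
from .stats import (
    CurvatureBinnedProfile,
    bin_and_block,
    default_edges,
    transform_block_means,
)
from .surface import SurfaceFit, periodic_delta

__all__ = [
    "LeafletCurvatureConvention",
    "ThicknessResult",
    "thickness_samples",
    "thickness_profile",
    "bilayer_area_density",
    "monolayer_area_density",
    "area_per_lipid",
    "lipid_curvatures",
]

LEAFLETS = ("upper", "lower")


@dataclass(frozen=True)
class LeafletCurvatureConvention:
    """Signed-curvature convention for single leaflets.

    ``upper_sign`` is the factor applied to the midplane curvature for the
    upper leaflet; the lower leaflet gets the opposite sign.  The default -1
    makes K > 0 wherever a leaflet's lipid-water interface is convex.
    """

    upper_sign: float = -1.0

    def sign(self, leaflet: str) -> float:
        if leaflet == "upper":
            return self.upper_sign
        if leaflet == "lower":
            return -self.upper_sign
        raise ValueError(f"unknown leaflet '{leaflet}'")

    def transform(self, K_mid: np.ndarray | float, leaflet: str) -> np.ndarray | float:
        return self.sign(leaflet) * K_mid

    def flipped(self) -> "LeafletCurvatureConvention":
        return LeafletCurvatureConvention(upper_sign=-self.upper_sign)


def _refine_closest(fit: SurfaceFit, px, pz, x_seed, half_width):
    """Vectorized ternary search for the x minimizing the periodic xz-distance
    from (px, pz) to the curve, within +-half_width of the seed."""
    lo = x_seed - half_width
    hi = x_seed + half_width

    def d2(x):
        dx = periodic_delta(px - x, fit.L_x)
        return dx**2 + (pz - np.asarray(fit.z(x))) ** 2

    for _ in range(40):
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        take_lo = d2(m1) < d2(m2)
        hi = np.where(take_lo, m2, hi)
        lo = np.where(take_lo, lo, m1)
    x_best = 0.5 * (lo + hi)
    return x_best, np.sqrt(d2(x_best))


@dataclass
class ThicknessResult:
    """Per-sample local thickness with its assigned midplane curvature."""

    K: np.ndarray          # signed midplane curvature at the assignment point
    D_PP: np.ndarray       # nm
    time: np.ndarray       # ns
    leaflet: np.ndarray    # sweep origin ('upper'/'lower')
    n_excluded: int        # degenerate segments dropped


def thickness_samples(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    delta_s: float = 0.1,
    max_angle_deg: float = 80.0,
) -> ThicknessResult:
    """Sweep both leaflet discretizations; for each arc point find the closest
    point on the opposing leaflet curve (discrete scan refined by bounded 1D
    minimization) and record the segment length as local thickness.

    Segments more than ``max_angle_deg`` away from the local leaflet normal
    (near-parallel to the surface) and segments of vanishing length are
    excluded and counted, as the construction presumes quasi-parallel curves.
    """
    Ks, Ds, Ts, Ls = [], [], [], []
    n_excl = 0
    for fr, ff in zip(frames, fits):
        disc_m = ff.disc("midplane", delta_s)
        mx, mz = disc_m.x, disc_m.z
        K_m = np.asarray(ff.midplane.curvature(disc_m.x))
        for leaf, opp in (("upper", "lower"), ("lower", "upper")):
            disc_a = ff.disc(leaf, delta_s)
            disc_b = ff.disc(opp, delta_s)
            fit_b = ff.get(opp)
            px, pz = disc_a.x, disc_a.z
            seed_idx = disc_b.nearest_index(px, pz)
            qx, dist = _refine_closest(fit_b, px, pz, disc_b.x[seed_idx], 1.5 * delta_s)
            qz = np.asarray(fit_b.z(qx))
            seg = np.column_stack([periodic_delta(qx - px, disc_a.L_x), qz - pz])
            seg_len = np.linalg.norm(seg, axis=1)
            normals = ff.get(leaf).normal(px)
            with np.errstate(invalid="ignore"):
                cos_ang = np.abs(np.sum(seg * normals, axis=1)) / np.where(seg_len > 0, seg_len, np.inf)
            ok = (seg_len > 10 * np.finfo(float).eps) & (
                cos_ang >= np.cos(np.deg2rad(max_angle_deg))
            )
            n_excl += int(np.sum(~ok))
            # assignment: midplane arc point nearest to the segment
            p = np.column_stack([px, pz])[ok]
            q = p + seg[ok]
            d = q - p                                            # (ns, 2)
            mdx = periodic_delta(mx[None, :] - p[:, 0:1], disc_a.L_x)
            mdz = mz[None, :] - p[:, 1:2]
            dd = np.sum(d**2, axis=1)[:, None]
            tpar = np.clip((mdx * d[:, 0:1] + mdz * d[:, 1:2]) / dd, 0.0, 1.0)
            dist_seg = (mdx - tpar * d[:, 0:1]) ** 2 + (mdz - tpar * d[:, 1:2]) ** 2
            nearest_m = np.argmin(dist_seg, axis=1)
            Ks.append(K_m[nearest_m])
            Ds.append(dist[ok])
            Ts.append(np.full(ok.sum(), fr.time))
            Ls.append(np.full(ok.sum(), leaf, dtype="U5"))
    return ThicknessResult(
        K=np.concatenate(Ks),
        D_PP=np.concatenate(Ds),
        time=np.concatenate(Ts),
        leaflet=np.concatenate(Ls),
        n_excluded=n_excl,
    )


def thickness_profile(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    delta_s: float = 0.1,
    edges: np.ndarray | None = None,
    n_blocks: int = 4,
    signed: bool = False,
) -> CurvatureBinnedProfile:
    """Binned thickness ``D_PP(K)``; by default against |K| (thickness is a
    bilayer property, symmetric under the global midplane sign flip)."""
    res = thickness_samples(frames, fits, delta_s)
    K = res.K if signed else np.abs(res.K)
    if edges is None:
        edges = default_edges(absolute=not signed)
    return bin_and_block(K, res.D_PP, res.time, edges, n_blocks,
                         name="D_PP", units="nm")


def _density_samples(frame, ff, lipid_sel, delta_s):
    """Counts of tail-terminal centers per midplane arc point, normalized by
    centers-per-lipid, as area density samples (lipids / nm^2)."""
    term = frame.role("tail_terminal")
    mask = np.isin(term.lipid_index, lipid_sel) if lipid_sel is not None else slice(None)
    coords = term.coords[mask]
    n_lip = lipid_sel.size if lipid_sel is not None else frame.n_lipids
    centers_per_lipid = coords.shape[0] / max(n_lip, 1)
    disc = ff.disc("midplane", delta_s)
    idx = disc.nearest_index(coords[:, 0], coords[:, 2])
    counts = np.bincount(idx, minlength=disc.n_points).astype(float)
    dS = frame.box[1] * delta_s
    rho = counts / (dS * centers_per_lipid)
    K_m = np.asarray(ff.midplane.curvature(disc.x))
    return K_m, rho


def bilayer_area_density(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    delta_s: float = 0.1,
    edges: np.ndarray | None = None,
    n_blocks: int = 4,
) -> CurvatureBinnedProfile:
    """Lipid number area density along the midplane vs. |K|, both leaflets
    pooled (lipids / nm^2)."""
    if edges is None:
        edges = default_edges(absolute=True)
    Ks, Vs, Ts = [], [], []
    for fr, ff in zip(frames, fits):
        K_m, rho = _density_samples(fr, ff, None, delta_s)
        Ks.append(np.abs(K_m))
        Vs.append(rho)
        Ts.append(np.full(rho.size, fr.time))
    return bin_and_block(
        np.concatenate(Ks), np.concatenate(Vs), np.concatenate(Ts), edges, n_blocks,
        name="bilayer_area_density", units="nm^-2",
    )


def monolayer_area_density(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    convention: LeafletCurvatureConvention | None = None,
    delta_s: float = 0.1,
    edges: np.ndarray | None = None,
    n_blocks: int = 4,
) -> CurvatureBinnedProfile:
    """Per-leaflet lipid area density along the midplane vs. leaflet-signed K,
    leaflets pooled after the sign transform."""
    convention = convention or LeafletCurvatureConvention()
    if edges is None:
        edges = default_edges()
    Ks, Vs, Ts = [], [], []
    for fr, ff in zip(frames, fits):
        for leaf in LEAFLETS:
            sel = fr.lipids_in_leaflet(leaf)
            K_m, rho = _density_samples(fr, ff, sel, delta_s)
            Ks.append(convention.transform(K_m, leaf))
            Vs.append(rho)
            Ts.append(np.full(rho.size, fr.time))
    return bin_and_block(
        np.concatenate(Ks), np.concatenate(Vs), np.concatenate(Ts), edges, n_blocks,
        name="monolayer_area_density", units="nm^-2",
    )


def area_per_lipid(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    convention: LeafletCurvatureConvention | None = None,
    delta_s: float = 0.1,
    edges: np.ndarray | None = None,
    n_blocks: int = 4,
) -> CurvatureBinnedProfile:
    """Interface area per lipid vs. leaflet-signed K.

    Phosphorus markers are binned to their own leaflet's arc points, each bin
    covering area ``dS = L_y * ds``; the bin curvature is the midplane
    curvature at the midplane point closest to the bin center, leaflet-signed.
    ``APL = dS / (mean markers per bin)``, the reciprocal taken per block so
    mean and SEM stay consistent.
    """
    convention = convention or LeafletCurvatureConvention()
    if edges is None:
        edges = default_edges()
    Ks, Vs, Ts = [], [], []
    dS = None
    for fr, ff in zip(frames, fits):
        dS = fr.box[1] * delta_s
        disc_m = ff.disc("midplane", delta_s)
        K_m_disc = np.asarray(ff.midplane.curvature(disc_m.x))
        for leaf in LEAFLETS:
            sel = fr.lipids_in_leaflet(leaf)
            disc = ff.disc(leaf, delta_s)
            markers = fr.markers[sel]
            idx = disc.nearest_index(markers[:, 0], markers[:, 2])
            counts = np.bincount(idx, minlength=disc.n_points).astype(float)
            near_m = disc_m.nearest_index(disc.x, disc.z)
            K = convention.transform(K_m_disc[near_m], leaf)
            Ks.append(K)
            Vs.append(counts)
            Ts.append(np.full(counts.size, fr.time))
    count_profile = bin_and_block(
        np.concatenate(Ks), np.concatenate(Vs), np.concatenate(Ts), edges, n_blocks,
        name="markers_per_bin", units="",
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return transform_block_means(
            count_profile, lambda m: np.where(m > 0, dS / m, np.nan),
            name="area_per_lipid", units="nm^2",
        )


def lipid_curvatures(
    frame: RoleTaggedFrame,
    ff: FrameFits,
    convention: LeafletCurvatureConvention | None = None,
    delta_s: float = 0.1,
    signed: bool = True,
) -> np.ndarray:
    """Per-lipid curvature label: midplane curvature at the arc point nearest
    each lipid's phosphorus marker in the xz-plane, leaflet-signed unless
    ``signed=False`` (then the raw midplane value is returned)."""
    disc_m = ff.disc("midplane", delta_s)
    idx = disc_m.nearest_index(frame.markers[:, 0], frame.markers[:, 2])
    K = np.asarray(ff.midplane.curvature(disc_m.x[idx]))
    if not signed:
        return K
    convention = convention or LeafletCurvatureConvention()
    if frame.leaflet is None:
        raise ValueError("leaflets not assigned")
    sgn = np.where(frame.leaflet == "upper", convention.sign("upper"), convention.sign("lower"))
    return sgn * K
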