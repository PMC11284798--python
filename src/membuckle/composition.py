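"""Curvature-resolved hydration, composition and Helfrich curvature sorting.

Hydration counts the water oxygens within a cutoff (default 0.3 nm, the first
minimum of the water-lipid radial distribution function) of each lipid's head
or terminal-tail heavy atoms.  For a two-component membrane, the local mole
fraction vs. curvature and the *enhancement ratio*

    ER(K) = ln[ (phi_b^u / phi_a^u)(K) / (phi_b^l / phi_a^l)(K) ]

quantify curvature sorting: under a Helfrich-type per-lipid bending energy
with moduli ``M_a, M_b`` (kBT nm^2) and spontaneous curvatures ``K0_a, K0_b``,
ER is linear in K with slope ``J_ab = 2 (M_b K0_b - M_a K0_a) / kBT``, so a
line fitted through the ER points yields the spontaneous curvature of one
species given the other's.  The upper leaflet is evaluated at leaflet
curvature +K and the lower at -K (opposite leaflets at the same spot carry
curvatures of equal magnitude and opposite sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .frames import FrameFits, RoleTaggedFrame
from .geometry import LeafletCurvatureConvention, lipid_curvatures
from .stats import CurvatureBinnedProfile, bin_and_block, default_edges
from .surface import periodic_delta

__all__ = [
    "hydration_counts",
    "hydration_profile",
    "mole_fraction_profile",
    "SortingFit",
    "enhancement_ratio",
    "spontaneous_curvature",
]

_REGION_ROLE = {"head": "head_heavy", "tail": "tail_heavy"}


def hydration_counts(frame: RoleTaggedFrame, region: str = "head", cutoff: float = 0.3) -> np.ndarray:
    """Water oxygens strictly within ``cutoff`` of any heavy atom of each
    lipid's head (or terminal tail) region; x/y-periodic minimum image."""
    if region not in _REGION_ROLE:
        raise ValueError("region must be 'head' or 'tail'")
    heavy = frame.role(_REGION_ROLE[region])
    waters = frame.role("water_oxygen").coords
    counts = np.zeros(frame.n_lipids, dtype=np.int64)
    if waters.shape[0] == 0:
        warnings.warn("no water oxygens in frame; hydration counts are all zero")
        return counts
    L_x, L_y, L_z = frame.box
    # periodic KD-tree in x and y; z padded so no spurious z-images appear
    boxsize = np.array([L_x, L_y, 1e6])
    tree = cKDTree(np.mod(waters, boxsize), boxsize=boxsize)
    cand = tree.query_ball_point(np.mod(heavy.coords, boxsize), r=cutoff * (1 + 1e-9))
    h_idx = np.repeat(np.arange(heavy.coords.shape[0]), [len(c) for c in cand])
    w_idx = np.fromiter((w for c in cand for w in c), dtype=np.int64, count=h_idx.size)
    if h_idx.size == 0:
        return counts
    d = heavy.coords[h_idx] - waters[w_idx]
    d[:, 0] = periodic_delta(d[:, 0], L_x)
    d[:, 1] = periodic_delta(d[:, 1], L_y)
    dist = np.linalg.norm(d, axis=1)
    keep = dist < cutoff  # strict: a water exactly at the cutoff is excluded
    pairs = np.unique(
        np.column_stack([heavy.lipid_index[h_idx[keep]], w_idx[keep]]), axis=0
    )
    np.add.at(counts, pairs[:, 0], 1)
    return counts


def hydration_profile(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    region: str = "head",
    cutoff: float = 0.3,
    convention: LeafletCurvatureConvention | None = None,
    edges: np.ndarray | None = None,
    n_blocks: int = 4,
    delta_s: float = 0.1,
) -> CurvatureBinnedProfile:
    """Mean per-lipid hydration number vs. leaflet-signed curvature, each
    lipid labeled by the midplane curvature at the point nearest its
    phosphorus marker."""
    convention = convention or LeafletCurvatureConvention()
    if edges is None:
        edges = default_edges()
    Ks, Vs, Ts = [], [], []
    for fr, ff in zip(frames, fits):
        counts = hydration_counts(fr, region, cutoff)
        K = lipid_curvatures(fr, ff, convention, delta_s)
        Ks.append(K)
        Vs.append(counts.astype(float))
        Ts.append(np.full(counts.size, fr.time))
    name = "H_H" if region == "head" else "H_T"
    return bin_and_block(
        np.concatenate(Ks), np.concatenate(Vs), np.concatenate(Ts), edges, n_blocks,
        name=name, units="waters/lipid",
    )


def mole_fraction_profile(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    species: str,
    convention: LeafletCurvatureConvention | None = None,
    edges: np.ndarray | None = None,
    n_blocks: int = 4,
    delta_s: float = 0.1,
) -> CurvatureBinnedProfile:
    """Mole fraction of ``species`` vs. leaflet-signed curvature, leaflets
    pooled after the sign transform."""
    convention = convention or LeafletCurvatureConvention()
    if edges is None:
        edges = default_edges()
    all_species = set()
    for fr in frames:
        all_species.update(np.unique(fr.species).tolist())
    if len(all_species) < 2:
        raise ValueError("mole fraction requires at least two species in the system")
    if species not in all_species:
        raise ValueError(f"species '{species}' not present (found {sorted(all_species)})")
    Ks, Vs, Ts = [], [], []
    for fr, ff in zip(frames, fits):
        K = lipid_curvatures(fr, ff, convention, delta_s)
        Ks.append(K)
        Vs.append((fr.species == species).astype(float))
        Ts.append(np.full(fr.n_lipids, fr.time))
    return bin_and_block(
        np.concatenate(Ks), np.concatenate(Vs), np.concatenate(Ts), edges, n_blocks,
        name=f"phi_{species}", units="",
    )


@dataclass
class SortingFit:
    """Enhancement-ratio points vs. curvature and the fitted line."""

    K: np.ndarray                 # bin centers used in the fit (1/nm)
    er: np.ndarray                # mean ER per bin
    er_sem: np.ndarray
    J_ab: float                   # slope, nm
    J_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    form: str = "odds"            # 'odds' (log odds ratio) or 'simple'
    n_bins_dropped: int = 0
    species_a: str = "a"
    species_b: str = "b"
    extras: dict = field(default_factory=dict)


def enhancement_ratio(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    species_a: str,
    species_b: str,
    convention: LeafletCurvatureConvention | None = None,
    edges: np.ndarray | None = None,
    n_blocks: int = 4,
    delta_s: float = 0.1,
    form: str = "odds",
) -> SortingFit:
    """Enhancement ratio vs. curvature with a weighted linear fit.

    Lipids of both leaflets are binned by the *upper-leaflet* curvature of
    their position along the membrane, so each bin compares the two leaflets
    at the same spot (leaflet curvatures +K and -K).  ER per block is computed
    from per-block species counts; bins missing any required count in a block
    are dropped with a warning.  The fit is weighted by the inverse variance
    of the block-mean ER.

    ``form='odds'`` uses the cross-leaflet log odds ratio (exactly linear in K
    under the Gibbs measure of the per-lipid bending energy);
    ``form='simple'`` uses ``ln(phi_b^u / phi_b^l)``.
    """
    if form not in ("odds", "simple"):
        raise ValueError("form must be 'odds' or 'simple'")
    convention = convention or LeafletCurvatureConvention()
    if edges is None:
        edges = default_edges()
    n_bins = edges.size - 1
    t_all = np.array([fr.time for fr in frames])
    t0, t1 = t_all.min(), t_all.max()
    span = max(t1 - t0, np.finfo(float).tiny)

    counts = np.zeros((n_bins, n_blocks, 2, 2))  # (bin, block, leaflet u/l, species a/b)
    for fr, ff in zip(frames, fits):
        K_loc = lipid_curvatures(fr, ff, convention=None, delta_s=delta_s, signed=False)
        K_loc = convention.transform(K_loc, "upper")
        bins = np.digitize(K_loc, edges) - 1
        blk = min(int(n_blocks * (fr.time - t0) / span), n_blocks - 1)
        ok = (bins >= 0) & (bins < n_bins)
        leaf_i = np.where(fr.leaflet == "upper", 0, 1)
        for sp_i, sp in enumerate((species_a, species_b)):
            sel = ok & (fr.species == sp)
            np.add.at(counts, (bins[sel], blk, leaf_i[sel], sp_i), 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "odds":
            er_blk = np.log(
                (counts[..., 0, 1] / counts[..., 0, 0])
                / (counts[..., 1, 1] / counts[..., 1, 0])
            )
        else:
            phi_u = counts[..., 0, 1] / (counts[..., 0, 0] + counts[..., 0, 1])
            phi_l = counts[..., 1, 1] / (counts[..., 1, 0] + counts[..., 1, 1])
            er_blk = np.log(phi_u / phi_l)
    er_blk[~np.isfinite(er_blk)] = np.nan

    n_present = np.sum(np.isfinite(er_blk), axis=1)
    usable = n_present >= 2
    n_dropped = int(np.sum(~usable & (counts.sum(axis=(1, 2, 3)) > 0)))
    if n_dropped:
        warnings.warn(f"{n_dropped} curvature bins dropped (zero counts in some block)")
    if np.sum(usable) < 3:
        raise ValueError("fewer than 3 usable curvature bins for the ER fit")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        er = np.nanmean(er_blk, axis=1)
        er_sd = np.nanstd(er_blk, axis=1, ddof=1)
    er_sem = er_sd / np.sqrt(n_present.clip(1))

    Kc = 0.5 * (edges[:-1] + edges[1:])[usable]
    y = er[usable]
    sem = er_sem[usable]
    w = np.where(sem > 0, 1.0 / sem**2, np.nan)
    if not np.all(np.isfinite(w)):
        w = np.ones_like(y)
    X = np.column_stack([np.ones_like(Kc), Kc])
    WX = X * w[:, None]
    cov = np.linalg.inv(X.T @ WX)
    beta = cov @ (WX.T @ y)
    resid = y - X @ beta
    ybar = np.sum(w * y) / np.sum(w)
    ss_res = np.sum(w * resid**2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    se = np.sqrt(np.diag(cov))
    return SortingFit(
        K=Kc, er=y, er_sem=sem,
        J_ab=float(beta[1]), J_se=float(se[1]),
        intercept=float(beta[0]), intercept_se=float(se[0]),
        r_squared=float(r2), form=form, n_bins_dropped=n_dropped,
        species_a=species_a, species_b=species_b,
    )


def spontaneous_curvature(
    fit: SortingFit,
    kappa: float,
    S_b: float,
    K0_a: float = 0.0,
    S_a: float | None = None,
) -> float:
    """Spontaneous curvature of species b from the fitted ER slope.

    With per-lipid moduli ``M = kappa * S`` (monolayer bending modulus kappa
    in kBT, per-lipid area S in nm^2) and ``J_ab = 2 (M_b K0_b - M_a K0_a)``
    in kBT = 1 units::

        K0_b = (J_ab / 2 + M_a K0_a) / M_b

    For ``K0_a = 0`` this reduces to ``K0_b = J_ab / (2 kappa S_b)``.  kappa
    has no safe universal default (it is force-field and composition
    dependent) and must be supplied.
    """
    if kappa <= 0 or S_b <= 0:
        raise ValueError("kappa and S_b must be positive")
    M_b = kappa * S_b
    M_a = kappa * S_a if S_a is not None else 0.0
    if K0_a != 0.0 and S_a is None:
        raise ValueError("S_a required when K0_a is nonzero")
    return (fit.J_ab / 2.0 + M_a * K0_a) / M_b
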