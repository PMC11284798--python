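"""Acyl-chain order parameters against the local normal, and curvature-labeled
lateral diffusion along the leaflet arc.

Order parameter: ``S = <(3 cos^2 theta - 1)/2>_K`` with theta the angle of a
chain bond vector (C-C or C-H) to the local bilayer normal at the midplane
point nearest the lipid's phosphorus marker.  Two equivalent evaluation paths
are provided — a direct dot product with the local normal, and rotating each
lipid's coordinates about the y-axis by the angle between the local normal and
the z-axis — and tests assert their agreement.

Diffusion: each lipid's phosphorus marker is projected to the arc-length
coordinate of its leaflet's discretized curve in every frame; one-dimensional
displacements ``ds(t) = s(t) - s(0)`` over 10 ns tracks give a mean squared
displacement per curvature label, and ``<ds^2> = 2 D t`` fitted over lag
times 5-10 ns (free intercept) yields ``D(K)`` in nm^2/ns
(1 nm^2/ns = 100 x 1e-7 cm^2/s).
"""

from __future__ import annotations

import numpy as np

from .frames import FrameFits, RoleTaggedFrame
from .geometry import LEAFLETS, LeafletCurvatureConvention, lipid_curvatures
from .stats import (
    CurvatureBinnedProfile,
    bin_and_block,
    default_edges,
    profile_from_block_values,
)

__all__ = [
    "p2_order",
    "order_parameter_profile",
    "diffusion_profile",
    "NM2_PER_NS_TO_1E7_CM2_PER_S",
]

#: multiply nm^2/ns by this to get units of 1e-7 cm^2/s
NM2_PER_NS_TO_1E7_CM2_PER_S = 100.0


def p2_order(vectors: np.ndarray, normals: np.ndarray, method: str = "dot") -> np.ndarray:
    """Per-vector P2 of the angle to the paired local normal.

    ``vectors`` (m, 3) need not be unit length; ``normals`` (m, 3) must be
    unit vectors in the xz-plane.  ``method='rotate'`` rotates each vector
    about the y-axis so its normal maps onto z, then reads the z-component —
    numerically equivalent to the dot product, kept as an independent path.
    """
    v = np.asarray(vectors, dtype=float)
    norm = np.linalg.norm(v, axis=1)
    if np.any(norm < 1e-12):
        raise ValueError("zero-length chain vector")
    n = np.asarray(normals, dtype=float)
    if method == "dot":
        cos_t = np.sum(v * n, axis=1) / norm
    elif method == "rotate":
        # angle of the local normal to the z-axis, rotation about y
        alpha = np.arctan2(-n[:, 0], n[:, 2])
        cos_t = (-v[:, 0] * np.sin(alpha) + v[:, 2] * np.cos(alpha)) / norm
    else:
        raise ValueError("method must be 'dot' or 'rotate'")
    return 1.5 * cos_t**2 - 0.5


def order_parameter_profile(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    chain: str,
    convention: LeafletCurvatureConvention | None = None,
    edges: np.ndarray | None = None,
    n_blocks: int = 4,
    delta_s: float = 0.1,
    method: str = "dot",
    absolute: bool = False,
) -> CurvatureBinnedProfile:
    """Chain order parameter S(K) for one named chain (e.g. sn1 / sn2).

    Each bond vector contributes one sample at its lipid's leaflet-signed
    curvature.  ``absolute=True`` reports |S| for comparison with deuterium
    order conventions that quote magnitudes.
    """
    convention = convention or LeafletCurvatureConvention()
    if edges is None:
        edges = default_edges()
    Ks, Vs, Ts = [], [], []
    for fr, ff in zip(frames, fits):
        if chain not in fr.chain_vectors:
            raise KeyError(f"frame has no chain vectors named '{chain}'")
        cv = fr.chain_vectors[chain]
        K_lip = lipid_curvatures(fr, ff, convention, delta_s)
        disc_m = ff.disc("midplane", delta_s)
        idx = disc_m.nearest_index(fr.markers[:, 0], fr.markers[:, 2])
        n2 = ff.midplane.normal(disc_m.x[idx])            # (n_lipids, 2) in xz
        n3 = np.column_stack([n2[:, 0], np.zeros(fr.n_lipids), n2[:, 1]])
        p2 = p2_order(cv.vectors(), n3[cv.lipid_index], method=method)
        Ks.append(K_lip[cv.lipid_index])
        Vs.append(p2)
        Ts.append(np.full(p2.size, fr.time))
    prof = bin_and_block(
        np.concatenate(Ks), np.concatenate(Vs), np.concatenate(Ts), edges, n_blocks,
        name=f"S_{chain}", units="",
    )
    if absolute:
        prof.mean = np.abs(prof.mean)
        prof.block_means = np.abs(prof.block_means)
    return prof


def _arc_coordinates(frames, fits, delta_s):
    """Per-frame arc coordinate s of every lipid's marker on its leaflet's
    discretized curve, plus the per-frame total arc lengths."""
    n_frames = len(frames)
    n_lip = frames[0].n_lipids
    s = np.full((n_frames, n_lip), np.nan)
    totals = {leaf: np.empty(n_frames) for leaf in LEAFLETS}
    leaf_lab = np.empty((n_frames, n_lip), dtype="U5")
    for i, (fr, ff) in enumerate(zip(frames, fits)):
        leaf_lab[i] = fr.leaflet
        for leaf in LEAFLETS:
            disc = ff.disc(leaf, delta_s)
            totals[leaf][i] = disc.total_length
            sel = fr.lipids_in_leaflet(leaf)
            idx = disc.nearest_index(fr.markers[sel, 0], fr.markers[sel, 2])
            s[i, sel] = disc.s[idx]
    return s, totals, leaf_lab


def diffusion_profile(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    convention: LeafletCurvatureConvention | None = None,
    lag_window: tuple[float, float] = (5.0, 10.0),
    track_length: float = 10.0,
    stride: int = 1,
    edges: np.ndarray | None = None,
    n_blocks: int = 4,
    delta_s: float = 0.1,
) -> CurvatureBinnedProfile:
    """Lateral diffusion coefficient D(K) from 1D arc displacements (nm^2/ns).

    Every ``stride``-th frame opens a track per lipid, labeled with the
    leaflet-signed curvature at the marker's position at the track origin;
    signed arc displacements are accumulated incrementally between consecutive
    frames (minimum-arc increment, so a wrap over the periodic curve cannot
    alias).  MSD(t) is fitted per curvature bin and per trajectory block over
    the lag window with a free intercept; D = slope / 2.  Tracks whose lipid
    changes leaflet are dropped.
    """
    convention = convention or LeafletCurvatureConvention()
    if edges is None:
        edges = default_edges()
    n_bins = edges.size - 1
    times = np.array([fr.time for fr in frames])
    if times.size < 2:
        raise ValueError("diffusion requires at least two frames")
    dt = float(np.median(np.diff(times)))
    if dt <= 0:
        raise ValueError("frames are not in increasing time order")
    if times[-1] - times[0] < track_length:
        raise ValueError("trajectory shorter than one track length")
    n_track = int(round(track_length / dt))
    lags = np.arange(1, n_track + 1)
    lag_t = lags * dt
    in_win = (lag_t >= lag_window[0] - 1e-9) & (lag_t <= lag_window[1] + 1e-9)
    if np.sum(in_win) < 3:
        raise ValueError("fewer than 3 lag points in the fit window; reduce frame spacing")
    win_lags = lags[in_win]
    win_t = lag_t[in_win]

    s, totals, leaf_lab = _arc_coordinates(frames, fits, delta_s)
    n_frames, n_lip = s.shape
    # unwrapped cumulative arc trajectory per lipid
    inc = np.diff(s, axis=0)
    for leaf in LEAFLETS:
        mask = leaf_lab[1:] == leaf
        tot = totals[leaf][1:, None]
        inc = np.where(mask, inc - np.round(inc / tot) * tot, inc)
    s_unw = np.concatenate([s[:1], s[:1] + np.cumsum(inc, axis=0)], axis=0)
    flips = np.concatenate(
        [np.zeros((1, n_lip), dtype=int), np.cumsum(leaf_lab[1:] != leaf_lab[:-1], axis=0)]
    )

    t0, t1 = times[0], times[-1]
    span = max(t1 - t0, np.finfo(float).tiny)
    msd_sum = np.zeros((n_bins, n_blocks, win_lags.size))
    msd_cnt = np.zeros((n_bins, n_blocks, win_lags.size))
    n_dropped = 0
    for o in range(0, n_frames - n_track, stride):
        K0 = lipid_curvatures(frames[o], fits[o], convention, delta_s)
        bins = np.digitize(K0, edges) - 1
        blk = min(int(n_blocks * (times[o] - t0) / span), n_blocks - 1)
        valid = (bins >= 0) & (bins < n_bins) & (flips[o + n_track] == flips[o])
        n_dropped += int(np.sum(flips[o + n_track] != flips[o]))
        for j, lag in enumerate(win_lags):
            disp2 = (s_unw[o + lag] - s_unw[o]) ** 2
            np.add.at(msd_sum, (bins[valid], blk, j), disp2[valid])
            np.add.at(msd_cnt, (bins[valid], blk, j), 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        msd = np.where(msd_cnt > 0, msd_sum / msd_cnt, np.nan)
    D_blocks = np.full((n_bins, n_blocks), np.nan)
    A = np.column_stack([np.ones(win_t.size), win_t])
    for b in range(n_bins):
        for k in range(n_blocks):
            y = msd[b, k]
            if np.all(np.isfinite(y)):
                beta, *_ = np.linalg.lstsq(A, y, rcond=None)
                D_blocks[b, k] = beta[1] / 2.0
    n_samples = msd_cnt[:, :, 0].sum(axis=1).astype(np.int64)
    prof = profile_from_block_values(edges, D_blocks, n_samples, name="D", units="nm^2/ns")
    return prof
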