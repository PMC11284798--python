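"""Pivotal-plane estimation from per-center density-curvature slopes.

The pivotal plane of a monolayer is the depth at which lateral lipid density
does not change upon bending.  For every tracked interaction center A (an
atom or bead at a characteristic depth ``z_A`` in the monolayer), a surface is
fitted per frame to that center's positions in the xz-plane, the center's area
density along its own surface is binned by leaflet-signed curvature, and a
line is fitted to the normalized density over a curvature window (default
-0.15 to 0.15 1/nm) giving a slope ``a_A``.  Centers shallower than the
pivotal plane are diluted by convex bending (``a_A < 0``), deeper ones are
compressed (``a_A > 0``); the zero crossing of a line through the
``(z_A, a_A)`` points is the pivotal height ``z_p`` above the midplane.

``z_A`` values are reference depths from flat-geometry input (a flat-membrane
run or a user table) — they are not inferred from the buckled trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import FrameFits, RoleTaggedFrame
from .geometry import LEAFLETS, LeafletCurvatureConvention
from .stats import bin_and_block, default_edges
from .surface import discretize, fit_surface

__all__ = [
    "center_density_slopes",
    "PivotalPlaneEstimate",
    "estimate_pivotal_depth",
    "pivotal_plane",
]


def _window_slope(Kc: np.ndarray, y: np.ndarray) -> float:
    """OLS slope of y on Kc; NaN-aware."""
    ok = np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    A = np.column_stack([np.ones(ok.sum()), Kc[ok]])
    beta, *_ = np.linalg.lstsq(A, y[ok], rcond=None)
    return float(beta[1])


def center_density_slopes(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    center_roles: list[str],
    convention: LeafletCurvatureConvention | None = None,
    window: tuple[float, float] = (-0.15, 0.15),
    delta_s: float = 0.1,
    bin_width: float = 0.02,
    n_blocks: int = 4,
    n_harmonics: int = 6,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-center slopes of (normalized) area density vs. leaflet-signed K.

    For each center role and leaflet, the center's own surface is fitted per
    frame and discretized; densities are per arc bin (``dS = L_y * ds``) and
    labeled with the midplane curvature at the nearest midplane arc point,
    leaflet-signed.  Densities are normalized to the K = 0 bin before the
    linear fit (so centers of different multiplicity are comparable), and a
    slope is fitted per trajectory block for the uncertainty.

    Returns a DataFrame with columns center, a_A, a_se and the per-block
    slopes (block_0 .. block_{n-1}).
    """
    convention = convention or LeafletCurvatureConvention()
    lo, hi = window
    edges = default_edges(k_max=max(abs(lo), abs(hi)) + 1e-9, width=bin_width)
    rows = []
    for role in center_roles:
        Ks, Vs, Ts = [], [], []
        for fr, ff in zip(frames, fits):
            ra = fr.role(role)
            disc_m = ff.disc("midplane", delta_s)
            K_m_disc = np.asarray(ff.midplane.curvature(disc_m.x))
            for leaf in LEAFLETS:
                sel = fr.lipids_in_leaflet(leaf)
                mask = np.isin(ra.lipid_index, sel)
                coords = ra.coords[mask]
                if coords.shape[0] < 2 * n_harmonics + 1:
                    raise ValueError(f"too few atoms of center '{role}' in {leaf} leaflet")
                cfit = fit_surface(coords[:, [0, 2]], fr.box[0], n_harmonics)
                cdisc = discretize(cfit, delta_s)
                idx = cdisc.nearest_index(coords[:, 0], coords[:, 2])
                counts = np.bincount(idx, minlength=cdisc.n_points).astype(float)
                rho = counts / (fr.box[1] * delta_s)
                near_m = disc_m.nearest_index(cdisc.x, cdisc.z)
                K = convention.transform(K_m_disc[near_m], leaf)
                Ks.append(K)
                Vs.append(rho)
                Ts.append(np.full(rho.size, fr.time))
        prof = bin_and_block(
            np.concatenate(Ks), np.concatenate(Vs), np.concatenate(Ts), edges, n_blocks,
            name=f"rho_{role}", units="nm^-2",
        )
        Kc = prof.centers
        in_win = (Kc >= lo) & (Kc <= hi)
        if not np.any(in_win & np.isfinite(prof.mean)):
            raise ValueError(f"curvature window {window} outside the sampled K range")
        ref_bin = prof.reference_bin()
        block = prof.block_means.copy()
        if normalize:
            block = block / block[ref_bin][None, :]
        block_slopes = np.array(
            [_window_slope(Kc[in_win], block[in_win, b]) for b in range(prof.n_blocks)]
        )
        good = np.isfinite(block_slopes)
        a_A = float(np.mean(block_slopes[good]))
        a_se = (
            float(np.std(block_slopes[good], ddof=1) / np.sqrt(good.sum()))
            if good.sum() > 1 else np.nan
        )
        row = {"center": role, "a_A": a_A, "a_se": a_se}
        row.update({f"block_{b}": block_slopes[b] for b in range(prof.n_blocks)})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PivotalPlaneEstimate:
    """Zero crossing of the line through the (z_A, a_A) points."""

    centers: np.ndarray     # center names
    z_A: np.ndarray         # nm, reference heights above the midplane
    a_A: np.ndarray         # density-curvature slopes
    z_p: float              # nm
    z_p_se: float
    line_slope: float
    line_intercept: float
    window: tuple[float, float] = (-0.15, 0.15)

    def ratio_to_monolayer(self, D_PP: float) -> float:
        """``2 z_p / D_PP``: 0.5 for a uniform elastic sheet, ~0.67 observed
        for phospholipid monolayers."""
        return 2.0 * self.z_p / D_PP


def _zero_crossing(z: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    A = np.column_stack([np.ones(z.size), z])
    beta, *_ = np.linalg.lstsq(A, a, rcond=None)
    b0, b1 = beta
    if abs(b1) < 1e-12 * max(1.0, float(np.max(np.abs(a))) if a.size else 1.0):
        raise ValueError("no pivotal plane in range: fitted a(z) line has zero slope")
    return -b0 / b1, b0, b1


def estimate_pivotal_depth(
    z_A: np.ndarray,
    a_A: np.ndarray,
    centers: np.ndarray | None = None,
    block_slopes: np.ndarray | None = None,
    window: tuple[float, float] = (-0.15, 0.15),
) -> PivotalPlaneEstimate:
    """Fit a line to the (z_A, a_A) points; its zero crossing is z_p.

    ``block_slopes`` (n_centers, n_blocks), if given, yields the uncertainty
    by repeating the fit per trajectory block.
    """
    z_A = np.asarray(z_A, dtype=float)
    a_A = np.asarray(a_A, dtype=float)
    if z_A.size < 3:
        raise ValueError("at least 3 centers required")
    if np.allclose(a_A, a_A[0]):
        raise ValueError("all slopes equal; cannot locate a zero crossing")
    z_p, b0, b1 = _zero_crossing(z_A, a_A)
    z_p_se = np.nan
    if block_slopes is not None:
        block_slopes = np.asarray(block_slopes, dtype=float)
        zps = []
        for b in range(block_slopes.shape[1]):
            ab = block_slopes[:, b]
            ok = np.isfinite(ab)
            if ok.sum() >= 3:
                try:
                    zps.append(_zero_crossing(z_A[ok], ab[ok])[0])
                except ValueError:
                    pass
        if len(zps) > 1:
            z_p_se = float(np.std(zps, ddof=1) / np.sqrt(len(zps)))
    return PivotalPlaneEstimate(
        centers=np.asarray(centers) if centers is not None else np.arange(z_A.size),
        z_A=z_A, a_A=a_A, z_p=float(z_p), z_p_se=z_p_se,
        line_slope=float(b1), line_intercept=float(b0), window=window,
    )


def pivotal_plane(
    frames: list[RoleTaggedFrame],
    fits: list[FrameFits],
    center_heights: dict[str, float],
    convention: LeafletCurvatureConvention | None = None,
    window: tuple[float, float] = (-0.15, 0.15),
    **kwargs,
) -> PivotalPlaneEstimate:
    """End-to-end pivotal-plane estimate: density slopes for every center role
    in ``center_heights`` (role -> flat-reference height z_A), then the zero
    crossing of the a(z) line."""
    roles = list(center_heights)
    df = center_density_slopes(frames, fits, roles, convention, window, **kwargs)
    n_blocks = sum(c.startswith("block_") for c in df.columns)
    blocks = df[[f"block_{b}" for b in range(n_blocks)]].to_numpy()
    return estimate_pivotal_depth(
        z_A=np.array([center_heights[r] for r in df["center"]]),
        a_A=df["a_A"].to_numpy(),
        centers=df["center"].to_numpy(),
        block_slopes=blocks,
        window=window,
    )
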