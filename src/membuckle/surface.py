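"""Periodic sinusoid-series surface model for buckled membranes.

A buckled bilayer simulated in an elongated box deforms along ``x`` only, so
every surface of interest (midplane, leaflet phosphate surfaces, per-atom
surfaces) is a periodic plane curve ``z = Z(x)`` with period ``L_x``.  This
module provides the geometric kernel used by every analysis stage:

* least-squares fitting of the harmonic series
  ``Z(x) = A_0 + sum_n A_n sin(2 pi n (x - x_n) / L_x)``,
* analytic first/second derivatives, signed curvature and local normals,
* reparameterization of the curve into points spaced by constant arc length,
* periodic nearest-point queries against the discretized curve.

Curvature is the signed plane-curve curvature ``K = Z'' / (1 + Z'^2)^{3/2}``:
negative at a crest (local maximum of Z), positive in a trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson, quad

__all__ = [
    "SurfaceFit",
    "ArcDiscretization",
    "fit_surface",
    "curvature",
    "local_normal",
    "discretize",
    "nearest_arc_point",
    "periodic_delta",
]

#: number of grid points used for arc-length quadrature / inversion
_ARC_GRID = 8192


def periodic_delta(dx: np.ndarray | float, period: float) -> np.ndarray | float:
    """Wrap coordinate differences into ``[-period/2, period/2)``."""
    return dx - period * np.round(np.asarray(dx, dtype=float) / period)


@dataclass(frozen=True)
class SurfaceFit:
    """Harmonic series ``Z(x) = A_0 + sum A_n sin(2 pi n (x - x_n) / L_x)``.

    Phases are gauge-fixed to ``A_n >= 0`` and ``x_n in [0, L_x / n)`` so two
    fits of the same curve are comparable term by term.
    """

    L_x: float
    A0: float
    amplitudes: np.ndarray  # (N,) A_n >= 0, nm
    phases: np.ndarray      # (N,) x_n in [0, L_x/n), nm
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "phases", np.asarray(self.phases, dtype=float))
        if self.amplitudes.size < 1:
            raise ValueError("at least one harmonic required")
        if self.amplitudes.shape != self.phases.shape:
            raise ValueError("amplitudes and phases must have equal length")
        if self.L_x <= 0:
            raise ValueError("period L_x must be positive")

    @property
    def n_harmonics(self) -> int:
        return self.amplitudes.size

    def _k(self) -> np.ndarray:
        n = np.arange(1, self.n_harmonics + 1)
        return 2.0 * np.pi * n / self.L_x

    def z(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        k = self._k()
        arg = k * (x[..., None] - self.phases)
        return self.A0 + np.sum(self.amplitudes * np.sin(arg), axis=-1)

    def dz(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        k = self._k()
        arg = k * (x[..., None] - self.phases)
        return np.sum(self.amplitudes * k * np.cos(arg), axis=-1)

    def d2z(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        k = self._k()
        arg = k * (x[..., None] - self.phases)
        return -np.sum(self.amplitudes * k**2 * np.sin(arg), axis=-1)

    def curvature(self, x: np.ndarray | float) -> np.ndarray | float:
        """Signed curvature ``K = Z'' / (1 + Z'^2)^(3/2)`` in 1/nm."""
        zp = self.dz(x)
        return self.d2z(x) / (1.0 + zp**2) ** 1.5

    def normal(self, x: np.ndarray | float) -> np.ndarray:
        """Unit normal ``(-Z', 1) / sqrt(1 + Z'^2)`` (positive z-component).

        Returned with shape ``(..., 2)`` for array input, ``(2,)`` for scalar.
        """
        zp = np.asarray(self.dz(x), dtype=float)
        norm = np.sqrt(1.0 + zp**2)
        return np.stack([-zp / norm, np.ones_like(zp) / norm], axis=-1)

    def arc_speed(self, x: np.ndarray | float) -> np.ndarray | float:
        """``ds/dx = sqrt(1 + Z'^2)``."""
        return np.sqrt(1.0 + np.asarray(self.dz(x), dtype=float) ** 2)

    def arc_length(self) -> float:
        """Total arc length over one period, by adaptive quadrature."""
        val, _ = quad(lambda t: float(self.arc_speed(t)), 0.0, self.L_x, limit=200)
        return val

    def to_table(self) -> "np.ndarray":
        """(n, A_n, x_n) rows for export; row n = 0 holds (0, A_0, 0)."""
        n = np.arange(0, self.n_harmonics + 1, dtype=float)
        amp = np.concatenate([[self.A0], self.amplitudes])
        pha = np.concatenate([[0.0], self.phases])
        return np.column_stack([n, amp, pha])


def fit_surface(points: np.ndarray, L_x: float, n_harmonics: int = 6) -> SurfaceFit:
    """Least-squares fit of the periodic harmonic series to ``(x, z)`` points.

    Each harmonic is linearized as ``a_n sin(k_n x) + b_n cos(k_n x)`` so the
    fit is an ordinary linear least-squares problem with a unique global
    minimum, then converted back to amplitude/phase form.

    Parameters
    ----------
    points : (n, 2) array of (x, z) positions in nm; x may be unwrapped.
    L_x : box period along x in nm.
    n_harmonics : number of harmonics (default 6).
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    x, z = pts[:, 0], pts[:, 1]
    if x.size < 2 * n_harmonics + 1:
        raise ValueError(
            f"need at least {2 * n_harmonics + 1} points for {n_harmonics} harmonics"
        )
    if np.ptp(x % L_x) < 1e-12:
        raise ValueError("degenerate design: all x values identical")

    k = 2.0 * np.pi * np.arange(1, n_harmonics + 1) / L_x
    design = np.empty((x.size, 2 * n_harmonics + 1))
    design[:, 0] = 1.0
    design[:, 1 : n_harmonics + 1] = np.sin(k * x[:, None])
    design[:, n_harmonics + 1 :] = np.cos(k * x[:, None])
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)

    a0 = coef[0]
    a = coef[1 : n_harmonics + 1]
    b = coef[n_harmonics + 1 :]
    amp = np.hypot(a, b)
    # a sin(kx) + b cos(kx) = A sin(k(x - x_n))  with  -k x_n = atan2(b, a)
    with np.errstate(invalid="ignore"):
        phase = np.where(amp > 0, -np.arctan2(b, a) / k, 0.0)
    period_n = L_x / np.arange(1, n_harmonics + 1)
    phase = np.mod(phase, period_n)
    resid = z - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    return SurfaceFit(L_x=float(L_x), A0=float(a0), amplitudes=amp, phases=phase,
                      residual_rms=rms)


def curvature(fit: SurfaceFit, x: np.ndarray | float) -> np.ndarray | float:
    """Signed curvature of the fitted curve at ``x`` (1/nm)."""
    return fit.curvature(x)


def local_normal(fit: SurfaceFit, x: np.ndarray | float) -> np.ndarray:
    """Unit normal in the xz-plane with positive z-component."""
    return fit.normal(x)


@dataclass
class ArcDiscretization:
    """Curve points spaced by constant arc length ``delta_s`` over one period."""

    x: np.ndarray        # (n,) x coordinates, in [0, L_x)
    z: np.ndarray        # (n,) curve heights
    s: np.ndarray        # (n,) cumulative arc length, s[0] = 0
    delta_s: float
    L_x: float
    total_length: float  # arc length of the full period (>= s[-1])
    fit: SurfaceFit | None = field(default=None, repr=False)

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.z])

    def nearest_index(self, p_x: np.ndarray, p_z: np.ndarray) -> np.ndarray:
        """Index of the arc point nearest each query, x-periodic, ties -> lowest.

        Vectorized over queries; memory O(n_query * n_points).
        """
        p_x = np.atleast_1d(np.asarray(p_x, dtype=float))
        p_z = np.atleast_1d(np.asarray(p_z, dtype=float))
        dx = periodic_delta(p_x[:, None] - self.x[None, :], self.L_x)
        dz = p_z[:, None] - self.z[None, :]
        return np.argmin(dx**2 + dz**2, axis=1)


def discretize(fit: SurfaceFit, delta_s: float = 0.1) -> ArcDiscretization:
    """Discretize the curve into points spaced by constant arc length.

    Arc length ``s(x)`` is tabulated by composite Simpson quadrature of
    ``sqrt(1 + Z'^2)`` on a dense grid, inverted by monotone interpolation and
    polished with one Newton step, so consecutive chord lengths match
    ``delta_s`` to well below 1e-4 nm for membrane-scale curvatures.
    """
    if delta_s <= 0:
        raise ValueError("delta_s must be positive")
    grid = np.linspace(0.0, fit.L_x, _ARC_GRID + 1)
    speed = fit.arc_speed(grid)
    s_grid = np.concatenate([[0.0], cumulative_simpson(speed, x=grid)])
    total = float(s_grid[-1])
    if delta_s >= total:
        raise ValueError("delta_s must be smaller than the curve period length")
    n_pts = int(np.floor(total / delta_s))
    s_target = np.arange(n_pts) * delta_s
    x_pts = np.interp(s_target, s_grid, grid)
    # Newton polish: s is strictly increasing with ds/dx = arc speed
    s_at = np.interp(x_pts, grid, s_grid)
    x_pts = x_pts - (s_at - s_target) / fit.arc_speed(x_pts)
    x_pts[0] = 0.0
    return ArcDiscretization(
        x=np.mod(x_pts, fit.L_x),
        z=np.asarray(fit.z(x_pts), dtype=float),
        s=s_target,
        delta_s=float(delta_s),
        L_x=fit.L_x,
        total_length=total,
        fit=fit,
    )


def nearest_arc_point(
    disc: ArcDiscretization, p: tuple[float, float] | np.ndarray, L_x: float | None = None
) -> tuple[int, float]:
    """Nearest discretized point to ``p = (x, z)`` under x-periodic distance.

    Returns ``(index, distance)``; ties break to the lowest index.
    """
    if disc.n_points == 0:
        raise ValueError("empty discretization")
    period = disc.L_x if L_x is None else L_x
    px, pz = float(p[0]), float(p[1])
    dx = periodic_delta(px - disc.x, period)
    d2 = dx**2 + (pz - disc.z) ** 2
    idx = int(np.argmin(d2))
    return idx, float(np.sqrt(d2[idx]))
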