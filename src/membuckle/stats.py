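"""Curvature binning, block-averaged uncertainties and profile normalization.

Every observable in the pipeline reduces to a stream of time-stamped samples
``(K, value, t)``.  Samples are histogrammed into curvature bins, and the
trajectory time range is split into a small number of equal blocks (four by
default); the reported mean of each bin is the mean of its per-block means and
the SEM is the standard deviation of the block means divided by ``sqrt(n)``.
Block averaging makes the SEM robust to temporal correlation between frames,
which plain per-sample standard errors badly underestimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CurvatureBinnedProfile",
    "default_edges",
    "bin_and_block",
    "normalize_to_flat",
    "denormalize",
    "merge_adjacent_bins",
]


def default_edges(k_max: float = 0.2, width: float = 0.02, absolute: bool = False) -> np.ndarray:
    """Default curvature bin edges: width 0.02 over [-k_max, k_max] (or [0, k_max])."""
    lo = 0.0 if absolute else -k_max
    n = int(round((k_max - lo) / width))
    return lo + width * np.arange(n + 1)


@dataclass
class CurvatureBinnedProfile:
    """An observable averaged in curvature bins with block-resampled errors.

    ``block_sums`` / ``block_counts`` keep the per-(bin, block) sufficient
    statistics so profiles can be re-binned or combined without the raw
    samples.  ``mean`` is NaN for bins with no samples; ``sem_reliable`` is
    False where at least one block is empty.
    """

    edges: np.ndarray              # (n_bins + 1,)
    mean: np.ndarray               # (n_bins,)
    sem: np.ndarray                # (n_bins,)
    n_samples: np.ndarray          # (n_bins,) int
    block_means: np.ndarray        # (n_bins, n_blocks), NaN where block empty
    block_sums: np.ndarray         # (n_bins, n_blocks)
    block_counts: np.ndarray       # (n_bins, n_blocks) int
    sem_reliable: np.ndarray       # (n_bins,) bool
    name: str = "observable"
    units: str = ""
    normalized: str | None = None  # None | "ratio" | "shift"
    reference: float | None = None
    _raw: "CurvatureBinnedProfile | None" = None

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def n_blocks(self) -> int:
        return self.block_means.shape[1]

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def reference_bin(self) -> int:
        """Bin used as the K = 0 reference: the bin containing 0, or the
        lowest bin for absolute-|K| profiles."""
        e = self.edges
        hit = np.nonzero((e[:-1] <= 0.0) & (0.0 < e[1:]))[0]
        if hit.size:
            return int(hit[0])
        if e[0] >= 0.0:
            return 0
        raise ValueError("no bin contains K = 0")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observable": self.name,
                "K_bin_lo": self.edges[:-1],
                "K_bin_hi": self.edges[1:],
                "mean": self.mean,
                "sem": self.sem,
                "n": self.n_samples,
                "normalized": self.normalized or "none",
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, ax=None, **kwargs):
        """Value vs. K with a shaded SEM band (paper-figure layout)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        good = np.isfinite(self.mean)
        c, m, s = self.centers[good], self.mean[good], self.sem[good]
        (line,) = ax.plot(c, m, marker="o", **kwargs)
        ax.fill_between(c, m - s, m + s, alpha=0.3, color=line.get_color())
        ax.set_xlabel(r"$K$ (nm$^{-1}$)")
        label = self.name if not self.units else f"{self.name} ({self.units})"
        ax.set_ylabel(label)
        return ax


def bin_and_block(
    K: np.ndarray,
    value: np.ndarray,
    time: np.ndarray,
    edges: np.ndarray,
    n_blocks: int = 4,
    name: str = "observable",
    units: str = "",
) -> CurvatureBinnedProfile:
    """Bin samples by curvature and estimate errors by block averaging.

    The trajectory time range is split into ``n_blocks`` equal spans; each
    bin's mean is the mean of its per-block means and its SEM the standard
    deviation of the block means over ``sqrt(n_blocks)``.  Samples outside
    the bin range are dropped.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    K = np.asarray(K, dtype=float).ravel()
    value = np.asarray(value, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    if not (K.size == value.size == time.size):
        raise ValueError("K, value and time must have equal length")
    edges = np.asarray(edges, dtype=float)
    n_bins = edges.size - 1

    bin_idx = np.digitize(K, edges) - 1
    in_range = (bin_idx >= 0) & (bin_idx < n_bins)
    # time -> block index over the full time range
    t0, t1 = (time.min(), time.max()) if time.size else (0.0, 1.0)
    span = max(t1 - t0, np.finfo(float).tiny)
    blk_idx = np.minimum((n_blocks * (time - t0) / span).astype(int), n_blocks - 1)

    sums = np.zeros((n_bins, n_blocks))
    counts = np.zeros((n_bins, n_blocks), dtype=np.int64)
    np.add.at(sums, (bin_idx[in_range], blk_idx[in_range]), value[in_range])
    np.add.at(counts, (bin_idx[in_range], blk_idx[in_range]), 1)
    return _profile_from_blocks(edges, sums, counts, name=name, units=units)


def _profile_from_blocks(
    edges: np.ndarray,
    sums: np.ndarray,
    counts: np.ndarray,
    name: str = "observable",
    units: str = "",
    normalized: str | None = None,
    reference: float | None = None,
) -> CurvatureBinnedProfile:
    with np.errstate(invalid="ignore", divide="ignore"):
        block_means = np.where(counts > 0, sums / counts, np.nan)
    n_blocks = sums.shape[1]
    n_present = np.sum(counts > 0, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(block_means, axis=1)
        sd = np.nanstd(block_means, axis=1, ddof=1)
    sem = np.where(n_present > 1, sd / np.sqrt(np.maximum(n_present, 1)), np.nan)
    return CurvatureBinnedProfile(
        edges=edges,
        mean=mean,
        sem=sem,
        n_samples=counts.sum(axis=1),
        block_means=block_means,
        block_sums=sums,
        block_counts=counts,
        sem_reliable=n_present == n_blocks,
        name=name,
        units=units,
        normalized=normalized,
        reference=reference,
    )


def profile_from_block_values(
    edges: np.ndarray,
    block_values: np.ndarray,
    n_samples: np.ndarray | None = None,
    name: str = "observable",
    units: str = "",
) -> CurvatureBinnedProfile:
    """Build a profile from per-(bin, block) derived values (e.g. a diffusion
    coefficient fitted per block), NaN marking empty blocks."""
    block_values = np.asarray(block_values, dtype=float)
    n_bins, n_blocks = block_values.shape
    present = np.isfinite(block_values)
    n_present = present.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(block_values, axis=1)
        sd = np.nanstd(block_values, axis=1, ddof=1)
    sem = np.where(n_present > 1, sd / np.sqrt(np.maximum(n_present, 1)), np.nan)
    if n_samples is None:
        n_samples = n_present
    return CurvatureBinnedProfile(
        edges=np.asarray(edges, dtype=float),
        mean=mean,
        sem=sem,
        n_samples=np.asarray(n_samples),
        block_means=block_values,
        block_sums=np.full_like(block_values, np.nan),
        block_counts=present.astype(np.int64),
        sem_reliable=n_present == n_blocks,
        name=name,
        units=units,
    )


def normalize_to_flat(profile: CurvatureBinnedProfile, mode: str = "ratio") -> CurvatureBinnedProfile:
    """Normalize a profile to its K = 0 bin.

    ``mode="ratio"`` divides by the reference-bin mean (profiles plotted as
    "normalized to 1 at K = 0"); ``mode="shift"`` subtracts it (used for
    thickness, plotted as a change from the flat value).  SEMs are propagated
    to first order treating bins as independent; the reference bin keeps its
    exact value (1 or 0) with zero SEM.
    """
    if profile.normalized is not None:
        raise ValueError("profile already normalized")
    if mode not in ("ratio", "shift"):
        raise ValueError("mode must be 'ratio' or 'shift'")
    ref_bin = profile.reference_bin()
    ref = profile.mean[ref_bin]
    ref_sem = profile.sem[ref_bin]
    if not np.isfinite(ref):
        raise ValueError("K = 0 reference bin is empty")
    if mode == "ratio":
        if ref == 0.0:
            raise ValueError("K = 0 reference mean is zero; cannot take ratio")
        mean = profile.mean / ref
        sem = np.abs(mean) * np.sqrt(
            np.where(profile.mean != 0, (profile.sem / profile.mean) ** 2, 0.0)
            + (np.where(np.isfinite(ref_sem), ref_sem, 0.0) / ref) ** 2
        )
        mean_ref, sem_ref = 1.0, 0.0
    else:
        mean = profile.mean - ref
        sem = np.sqrt(profile.sem**2 + np.where(np.isfinite(ref_sem), ref_sem, 0.0) ** 2)
        mean_ref, sem_ref = 0.0, 0.0
    mean = mean.copy()
    sem = sem.copy()
    mean[ref_bin], sem[ref_bin] = mean_ref, sem_ref
    out = replace(profile, mean=mean, sem=sem, normalized=mode, reference=float(ref))
    out._raw = profile
    return out


def denormalize(profile: CurvatureBinnedProfile) -> CurvatureBinnedProfile:
    """Undo :func:`normalize_to_flat`, restoring the original profile."""
    if profile.normalized is None:
        raise ValueError("profile is not normalized")
    if profile._raw is not None:
        return profile._raw
    if profile.normalized == "ratio":
        mean = profile.mean * profile.reference
    else:
        mean = profile.mean + profile.reference
    return replace(profile, mean=mean, normalized=None, reference=None)


def transform_block_means(
    profile: CurvatureBinnedProfile, func, name: str | None = None, units: str | None = None
) -> CurvatureBinnedProfile:
    """Map per-block means through ``func`` and recompute mean/SEM.

    Used for observables defined as a function of a binned mean (e.g. area per
    lipid = bin area / mean marker count): applying the transform per block
    keeps the mean and the SEM coming from the same estimator.  The returned
    profile no longer carries poolable block sums and cannot be re-merged.
    """
    block_means = func(profile.block_means)
    n_present = np.sum(np.isfinite(block_means), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(block_means, axis=1)
        sd = np.nanstd(block_means, axis=1, ddof=1)
    sem = np.where(n_present > 1, sd / np.sqrt(np.maximum(n_present, 1)), np.nan)
    return replace(
        profile,
        mean=mean,
        sem=sem,
        block_means=block_means,
        block_sums=np.full_like(profile.block_sums, np.nan),
        sem_reliable=n_present == profile.n_blocks,
        name=name if name is not None else profile.name,
        units=units if units is not None else profile.units,
    )


def merge_adjacent_bins(profile: CurvatureBinnedProfile, factor: int = 2) -> CurvatureBinnedProfile:
    """Merge runs of ``factor`` adjacent bins, recomputing block statistics
    from the stored per-(bin, block) sums so the result is identical to
    binning the original samples with the coarser edges."""
    if profile.n_bins % factor != 0:
        raise ValueError("n_bins must be divisible by factor")
    n_new = profile.n_bins // factor
    edges = profile.edges[::factor]
    sums = profile.block_sums.reshape(n_new, factor, -1).sum(axis=1)
    counts = profile.block_counts.reshape(n_new, factor, -1).sum(axis=1)
    return _profile_from_blocks(edges, sums, counts, name=profile.name, units=profile.units)
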