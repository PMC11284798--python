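import numpy as np
import pytest

from membuckle import fit_frames
from membuckle.synthetic import GeneratorSpec, generate


@pytest.fixture(scope="session")
def small_run():
    """A small two-component buckled run with chains, waters and extra
    centers — shared by tests that only need a structurally complete system."""
    spec = GeneratorSpec(
        n_lipids=200,
        n_frames=8,
        seed=101,
        phi_b=0.4,
        centers_heights=(0.4, 0.9, 1.4),
        hh_slope=1.25,
        s_slope=0.4,
    )
    frames, truth = generate(spec)
    fits = fit_frames(frames)
    return spec, frames, truth, fits


@pytest.fixture(scope="session")
def flat_run():
    """A flat (zero-amplitude) single-component membrane."""
    spec = GeneratorSpec(
        n_lipids=128,
        n_frames=4,
        seed=7,
        amplitude=0.0,
        include_waters=False,
        include_chains=False,
        jitter=0.0,
    )
    frames, truth = generate(spec)
    fits = fit_frames(frames)
    return spec, frames, truth, fits


def weighted_profile_mean(profile):
    """Sample-weighted overall mean of a binned profile."""
    ok = np.isfinite(profile.mean)
    return float(
        np.sum(profile.mean[ok] * profile.n_samples[ok]) / np.sum(profile.n_samples[ok])
    )
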