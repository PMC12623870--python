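import numpy as np
import pytest

from aidquant.synthetic import (KineticsSpec, PunctumSpec, SceneSpec,
                                simulate_culture_movie)


def place_positions(n, shape, min_dist=10, margin=10, seed=0):
    """Random punctum positions with a minimum pairwise distance."""
    rng = np.random.default_rng(seed)
    pos = []
    while len(pos) < n:
        r = int(rng.integers(margin, shape[0] - margin))
        c = int(rng.integers(margin, shape[1] - margin))
        if all(np.hypot(r - rr, c - cc) >= min_dist for rr, cc in pos):
            pos.append((r, c))
    return pos


def standard_scene(n_puncta=30, shape=(192, 192), amplitude=100.0,
                   f_major=0.9, tau_major=3.7, tau_minor=37.0,
                   background=10.0, gaussian_sd=0.0, seed=1,
                   times=None, events=None):
    """A culture movie scene at the default study conditions."""
    times = times or tuple(float(t) for t in range(-2, 17))
    pos = place_positions(n_puncta, shape, seed=seed)
    events = events or {}
    puncta = [
        PunctumSpec(
            position=p,
            kinetics={"target": KineticsSpec(
                amplitude=amplitude, f_major=f_major,
                tau_major=tau_major, tau_minor=tau_minor, t_inducer=0.0,
            )},
            **events.get(i, {}),
        )
        for i, p in enumerate(pos)
    ]
    return SceneSpec(
        shape=shape, n_z=3, puncta=puncta,
        background={"target": background},
        gaussian_sd=gaussian_sd, times_h=times, seed=seed,
    )


@pytest.fixture(scope="session")
def noiseless_movie():
    spec = standard_scene(n_puncta=12, shape=(128, 128))
    return simulate_culture_movie(spec)


@pytest.fixture(scope="session")
def noisy_movie():
    # SNR 10: amplitude 100, gaussian sd 10
    spec = standard_scene(gaussian_sd=10.0, seed=2)
    return simulate_culture_movie(spec)
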