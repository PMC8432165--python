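import numpy as np
import pytest

import bvcsr


@pytest.fixture(scope="session")
def square_env():
    return bvcsr.build_environment("square")


@pytest.fixture(scope="session")
def small_pop():
    """Reduced population (4 distances x 8 angles) for fast unit tests."""
    return bvcsr.make_population(
        d_levels=np.geomspace(0.08, 0.6, 4), n_angles=8, n_dirs=120
    )


@pytest.fixture(scope="session")
def small_fmap(square_env, small_pop):
    return bvcsr.feature_map(small_pop, square_env)


@pytest.fixture(scope="session")
def small_learned(square_env, small_pop, small_fmap):
    """10 simulated minutes of foraging + TD learning with the small population."""
    traj = bvcsr.simulate_trajectory(square_env, 600.0, seed=7)
    sm = bvcsr.learn_sr(small_fmap, traj)
    return traj, sm


def hex_pattern(n=60, scale=0.3, bin_size=0.02, rot=0.0, kind="hex", noise=0.0, seed=0):
    """Analytic periodic rate map: 3-wave hexagonal or 2-wave square lattice."""
    xs = (np.arange(n) + 0.5) * bin_size
    gx, gy = np.meshgrid(xs, xs)
    k = 2 * np.pi / scale
    angs = [0, np.pi / 3, 2 * np.pi / 3] if kind == "hex" else [0, np.pi / 2]
    vals = np.zeros_like(gx)
    for a in angs:
        vals += np.cos(k * np.cos(a + rot) * gx + k * np.sin(a + rot) * gy)
    if noise:
        vals += np.random.default_rng(seed).normal(0, noise, vals.shape)
    vals -= vals.min()
    vals /= vals.max()
    return bvcsr.RateMap(
        values=vals, mask=np.ones_like(vals, bool), bin_size=bin_size,
        origin=bvcsr.Point(0.0, 0.0),
    )
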