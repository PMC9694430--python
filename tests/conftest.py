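import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import expit

import kinscreen as ks

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def noiseless_params():
    """Pure sigmoid over the standard 25-95 degC ramp, no decay, no noise."""
    return ks.CurveParams(noise_sd=0.0, decay_onset=float("inf"))


@pytest.fixture
def noiseless_curve(noiseless_params):
    return ks.simulate_curve(noiseless_params, seed=0)


@pytest.fixture
def small_screen():
    """Small Tm-level simulated screen with a few planted binders."""
    scenario = dataclasses.replace(
        ks.ScreenScenario(),
        n_kinases=6,
        n_compounds=40,
        n_dmso_wells=12,
        binder_tail_fraction=0.1,
        seed=11,
    )
    return ks.simulate_screen(scenario)


@pytest.fixture(scope="session")
def kinome_sim():
    """Full-size simulated kinome (fast: plain table construction)."""
    return ks.simulate_kinome(dataclasses.replace(ks.KinomeScenario(), seed=17))


def boltzmann_grid_oracle(t, f, tm_lo, tm_hi):
    """Exhaustive grid search for the least-squares sigmoid Tm.

    For each (tm, slope) grid point the two baselines are solved by linear
    least squares in closed form; a coarse 0.1-step sweep over the full
    ranges is refined to 0.01 steps around the coarse minimiser.  Independent
    of the package's optimizer path.
    """
    t = np.asarray(t, float)
    f = np.asarray(f, float)

    def sweep(tm_grid, slope_grid):
        best = (np.inf, np.nan, np.nan)
        n = len(t)
        for slope in slope_grid:
            x = expit((t[None, :] - tm_grid[:, None]) / slope)
            sx = x.sum(axis=1)
            sxx = (x * x).sum(axis=1)
            sy = f.sum()
            sxy = x @ f
            det = n * sxx - sx**2
            with np.errstate(divide="ignore", invalid="ignore"):
                b = (n * sxy - sx * sy) / det
                a = (sy - b * sx) / n
            sse = ((f[None, :] - (a[:, None] + b[:, None] * x)) ** 2).sum(axis=1)
            sse[~np.isfinite(sse)] = np.inf
            i = int(np.argmin(sse))
            if sse[i] < best[0]:
                best = (float(sse[i]), float(tm_grid[i]), float(slope))
        return best

    coarse = sweep(np.arange(tm_lo, tm_hi + 1e-9, 0.1), np.arange(0.5, 10.0 + 1e-9, 0.1))
    _, tm_c, slope_c = coarse
    fine = sweep(
        np.arange(max(tm_lo, tm_c - 0.3), min(tm_hi, tm_c + 0.3) + 1e-9, 0.01),
        np.arange(max(0.5, slope_c - 0.2), min(10.0, slope_c + 0.2) + 1e-9, 0.01),
    )
    return fine[1], fine[2]
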