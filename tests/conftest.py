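"""Shared fixtures.

The expensive replicate batches (parameter-recovery and null-calibration
simulations) are session-scoped so every test that needs replicate fits
shares one computation.  Problem sizes are chosen to exercise the
documented study designs at desk scale; optimizer start grids are thinned
through the public FitOptions knob where the full default grid would be
redundant for well-identified simulated data.
"""

from __future__ import annotations

import numpy as np
import pytest

import continuitest as ct

FIG2_TRUTH = dict(t1=0.02, t2=0.05)


def make_options(n_t_starts: int = 2) -> ct.FitOptions:
    """Thinned deterministic start grid for replicate-loop fits."""
    grids = {1: (0.03,), 2: (0.01, 0.1), 3: (0.005, 0.05, 0.5)}
    grid = grids[n_t_starts]
    return ct.FitOptions(t1_starts=grid, t2_starts=grid, eps_starts=(0.01,))


def simulate_benchmark(rep: int, m: int, coverage: float, L: int = 20_000,
                       c: float = 0.0, seed_tag: int = 7) -> ct.Dataset:
    """One replicate of the standard benchmark design (t1=0.02, t2=0.05)."""
    demo = ct.DemographyConfig()  # split 400 gen, Ne 10k/1k, sample age 300
    cfg = ct.ReadSimConfig(m=m, coverage=coverage, eps=0.01, c=c, L=L)
    rng = np.random.default_rng([seed_tag, rep])
    return ct.simulate_dataset(demo, cfg, rng=rng)


@pytest.fixture(scope="session")
def fig2_fits():
    """20 replicate full-model fits: 5 diploids at 4x, 20k sites."""
    options = make_options(2)
    fits = []
    for rep in range(20):
        data = simulate_benchmark(rep, m=5, coverage=4.0)
        fits.append(ct.fit_full(data, options))
    return fits


@pytest.fixture(scope="session")
def null_fits():
    """200 replicate (full, null) fit pairs on data simulated under continuity.

    Design: t2 = 0 with the benchmark modern branch (t1 = 0.02), one
    diploid at 2x, 5,000 segregating sites per replicate.
    """
    demo = ct.DemographyConfig(tau2=0.0)
    cfg = ct.ReadSimConfig(m=1, coverage=2.0, eps=0.01, L=5_000)
    options = make_options(1)
    pairs = []
    for rep in range(200):
        rng = np.random.default_rng([11, rep])
        data = ct.simulate_dataset(demo, cfg, rng=rng)
        full = ct.fit_full(data, options)
        null = ct.fit_null(data, options)
        pairs.append((full, null))
    return pairs


@pytest.fixture()
def small_dataset():
    """A quick, moderately informative dataset for unit-level fitting tests."""
    data = simulate_benchmark(0, m=2, coverage=1.0, L=2_000, seed_tag=3)
    return data
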