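"""Shared fixtures: small synthetic registers and fitted bundles.

Register sizes here are deliberately modest so the whole suite stays fast;
statistical checks that need large n build their own cohorts.
"""

from __future__ import annotations

import numpy as np
import pytest

from strokecea.pipeline import AnalysisInputs, fit_period
from strokecea.synthetic_data import default_config, generate_cohort


@pytest.fixture(scope="session")
def register_before():
    return generate_cohort(default_config("before", n_patients=800, seed=101))


@pytest.fixture(scope="session")
def register_after():
    return generate_cohort(default_config("after", n_patients=1200, seed=102))


@pytest.fixture(scope="session")
def fits_before(register_before):
    return fit_period(register_before)


@pytest.fixture(scope="session")
def fits_after(register_after):
    return fit_period(register_after)


@pytest.fixture(scope="session")
def analysis_inputs(fits_before, fits_after):
    return AnalysisInputs(fits_before=fits_before, fits_after=fits_after)


def microsimulate(schedule, n_walkers: int, seed: int) -> np.ndarray:
    """Independent oracle for the cohort model: count-based microsimulation.

    Walkers move through the same per-day matrices by multinomial sampling;
    returns occupancy counts with shape (n_days + 1, n_states).
    """
    rng = np.random.default_rng(seed)
    n = len(schedule.states)
    counts = np.zeros(n, dtype=np.int64)
    init = rng.multinomial(n_walkers, schedule.initial)
    counts[:] = init
    occ = np.zeros((schedule.n_days + 1, n), dtype=np.int64)
    occ[0] = counts
    for t in range(schedule.n_days):
        nxt = np.zeros(n, dtype=np.int64)
        for s in range(n):
            if counts[s] > 0:
                nxt += rng.multinomial(counts[s], schedule.matrices[t, s])
        counts = nxt
        occ[t + 1] = counts
    return occ
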