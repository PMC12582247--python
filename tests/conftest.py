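"""Shared fixtures: small simulated cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import stablegait as sg


@pytest.fixture(scope="session")
def biped_profile():
    return sg.builtin_profile("biped")


@pytest.fixture(scope="session")
def feedback_cohort(biped_profile):
    """Four biped individuals with active feedback (G=0.4), processed."""
    params = sg.WalkerParams(profile=biped_profile, seed=42)
    sims = sg.simulate_individuals(params, 4, 260.0)
    cycles = sg.process_bouts([s.bout for s in sims], biped_profile)
    dev = sg.compute_deviations(cycles)
    return {"params": params, "sims": sims, "cycles": cycles, "dev": dev}


@pytest.fixture(scope="session")
def null_cohort(biped_profile):
    """Feedforward-only individuals (G=0), processed."""
    params = sg.WalkerParams(profile=biped_profile, seed=43, gain=0.0)
    sims = sg.simulate_individuals(params, 4, 260.0)
    cycles = sg.process_bouts([s.bout for s in sims], biped_profile)
    dev = sg.compute_deviations(cycles)
    return {"params": params, "sims": sims, "cycles": cycles, "dev": dev}


@pytest.fixture(scope="session")
def clean_sim(biped_profile):
    """One noiseless-observation bout with ground truth, for fidelity checks."""
    params = sg.WalkerParams(profile=biped_profile, seed=7, sigma_obs=0.0)
    return sg.simulate_walker(params, 300.0)


def synthetic_deviation_set(n=200, m=11, gains=(0.4, 0.0, 0.0, 0.0),
                            noise=0.0, seed=0, leg="left", animal="a0"):
    """Hand-built DeviationSet whose dP is an exact (or noisy) linear
    function of the body-state channels -- an oracle for the feedback fits."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    dQ = rng.normal(size=(n, m, 4))
    dQt = rng.normal(size=(n, m, 4))
    gains = np.asarray(gains)
    dP_y = dQ[:, m // 2, :] @ gains + noise * rng.normal(size=n)
    dP = np.column_stack([rng.normal(size=n), dP_y])
    index = pd.DataFrame({
        "animal_id": animal, "leg": leg, "bout_id": "b0",
        "cycle_index": np.arange(n), "v_hat": 1.0, "duration": 1.0,
        "contact_time": np.arange(n, dtype=float),
        "reference_side": np.where(np.arange(n) % 2 == 0, 1.0, -1.0),
        "extrapolated": False,
    })
    return sg.DeviationSet(
        index=index, dQ=dQ, dQt=dQt, dP=dP, dDur=np.zeros(n),
        dWidth=np.zeros(n), phase_grid=np.linspace(0, 1, m),
        Q_channels=("body:x", "body:y", "body:vx", "body:vy"),
        phi_swing={leg: 0.6},
    )
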