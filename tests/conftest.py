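import numpy as np
import pytest

import optobalance as ob


@pytest.fixture(scope="session")
def architectures():
    """All shipped circuit fixtures, loaded once."""
    return {name: ob.load_architecture(name) for name in ob.FIXTURE_NAMES}


@pytest.fixture(scope="session")
def baseline_run(architectures):
    """One balanced baseline run of the V1-like circuit at small scale,
    shared by the activity-statistics tests."""
    spec, sizes, opto = architectures["model1_nonparadox"]
    s = sizes.scaled(N=3072, K=128)
    cfg = ob.SimConfig(dt=0.02, duration=4000.0, warmup=500.0, seed=1)
    return spec, ob.simulate(spec, s, opto, config=cfg)


@pytest.fixture(scope="session")
def paradox_sweep_small(architectures):
    """Small intensity sweep of the paradoxical V1-like parameter set with
    spikes kept, shared by the simulation-to-recording pipeline tests.

    The probe intensity (Gamma = 20 mW/mm^2, photocurrent ~30 nA/cm^2) sits
    well inside the all-active segment of the mean-field solution, where the
    predicted PV-rate suppression is large.
    """
    spec, sizes, opto = architectures["model1_paradox"]
    s = sizes.scaled(N=2400, K=100)
    cfg = ob.SimConfig(dt=0.02, duration=5400.0, warmup=500.0, seed=7)
    sweep = ob.intensity_sweep_sim(spec, s, opto, [0.0, 20.0], cfg, keep_spikes=True)
    return spec, sweep


@pytest.fixture(scope="session")
def model2_sweep_small(architectures):
    """Small intensity sweep of the SOM-X circuit (proportional PC/PV
    suppression), shared by the orchestration tests."""
    spec, sizes, opto = architectures["model2"]
    s = sizes.scaled(N=2400, K=100)
    cfg = ob.SimConfig(dt=0.02, duration=4000.0, warmup=500.0, seed=9)
    sweep = ob.intensity_sweep_sim(spec, s, opto, [0.0, 20.0], cfg)
    return spec, sweep


def brute_force_states(A, c, rate_tol=1e-12, input_tol=1e-12):
    """Independent exhaustive enumeration of consistent balanced states:
    try every active subset, solve the restricted linear system directly,
    reject negative rates or depolarizing silent inputs."""
    from itertools import combinations

    n = len(c)
    found = []
    for k in range(n, -1, -1):
        for act in combinations(range(n), k):
            act = list(act)
            r = np.zeros(n)
            if act:
                block = A[np.ix_(act, act)]
                if abs(np.linalg.det(block)) < 1e-10:
                    continue
                r[act] = np.linalg.solve(block, -np.asarray(c)[act])
                if np.any(r[act] <= rate_tol):  # active populations fire strictly
                    continue
            sil = [i for i in range(n) if i not in act]
            h = np.asarray(c)[sil] + A[np.ix_(sil, act)] @ r[act]
            if np.any(h >= input_tol):
                continue
            found.append((frozenset(act), r))
    return found
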