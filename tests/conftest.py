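import numpy as np
import pytest

import specdcm as sd


@pytest.fixture(scope="session")
def benchmark_conn():
    return sd.four_node_benchmark()


@pytest.fixture(scope="session")
def hemo4():
    return sd.HemodynamicParams.defaults(4)


@pytest.fixture(scope="session")
def grid_tr2():
    return sd.default_grid(2.0)


@pytest.fixture(scope="session")
def benchmark_run():
    """One standard 512-scan simulated run (shared, read-only)."""
    return sd.simulate_bold(sd.benchmark_spec(seed=11))


@pytest.fixture(scope="session")
def benchmark_posterior(benchmark_run):
    """Inversion of the shared 512-scan run (expensive; computed once)."""
    return sd.invert_timeseries(benchmark_run.bold, benchmark_run.ground_truth.TR)


@pytest.fixture(scope="session")
def replicated_inversions():
    """Sixteen seeded 384-scan replications of the standard protocol, each
    simulated and inverted; shared by the accuracy and coverage checks."""
    ss = np.random.SeedSequence(20240384)
    out = []
    for child in ss.spawn(16):
        seed = int(child.generate_state(1)[0] % 2**31)
        ds = sd.simulate_bold(sd.benchmark_spec(seed=seed, n_scans=384))
        post = sd.invert_timeseries(ds.bold, 2.0)
        out.append((ds, post))
    return out
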