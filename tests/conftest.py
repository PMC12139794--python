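from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hydrosite import make_thermo
from hydrosite import sitefinder, synth, wtcalc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: fixed seed for the benchmark recovery run; any small integer works,
#: the tolerances are not seed-tuned.
BENCHMARK_SEED = 11


@pytest.fixture(scope="session")
def thermo300():
    return make_thermo(300.0, 0.033)


@pytest.fixture(scope="session")
def planted_benchmark(thermo300):
    """Five planted Gaussian sites over bulk, 20,000 frames, run through
    the full site-finding and WT-scoring pipeline once per session."""
    spec = synth.benchmark_spec(seed=BENCHMARK_SEED, n_frames=20000)
    traj = synth.generate_trajectory(spec)
    sites = sitefinder.find_sites(traj, spec.solute, max_sites=5)
    scored = wtcalc.score_sites(traj, sites, thermo300)
    expected = [
        synth.expected_wt(s, thermo300, spec.n_frames,
                          bulk_density=spec.bulk_density)
        for s in spec.sites
    ]
    return {
        "spec": spec,
        "traj": traj,
        "sites": sites,
        "scored": scored,
        "expected_wt": expected,
        "truth": np.array([s.center for s in spec.sites]),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
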