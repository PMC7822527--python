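import numpy as np
import pytest
from scipy.signal import oaconvolve

import dyadeda as dd


@pytest.fixture(scope="session")
def kernel():
    return dd.bateman_kernel(0.75, 2.0, fs=128.0)


@pytest.fixture(scope="session")
def peak_kernel(kernel):
    """Unit-peak Bateman shape for forward synthesis."""
    return kernel.samples / kernel.samples.max()


def make_trace(impulses, fs=128.0, duration=40.0, tonic=2.0, peak_kernel=None,
               pid="p1", dyad="d1"):
    """Forward-simulate a trace from (time, amplitude) impulses."""
    n = int(duration * fs)
    imp = np.zeros(n)
    for t, a in impulses:
        imp[int(round(t * fs))] += a
    if peak_kernel is None:
        k = dd.bateman_kernel(fs=fs)
        peak_kernel = k.samples / k.samples.max()
    phasic = oaconvolve(imp, peak_kernel)[:n]
    return dd.SCTrace(participant_id=pid, dyad_id=dyad, fs=fs,
                      samples=tonic + phasic)


@pytest.fixture(scope="session")
def small_bundle():
    """A 2-dyad simulated study reused by pipeline-level tests."""
    cfg = dd.SimConfig(n_dyads=2, n_mixed_dyads=1, events_per_dyad=8,
                       task_duration=220.0, seed=123)
    return dd.simulate_study(cfg)


@pytest.fixture()
def study_dir(tmp_path):
    """The same small study written to disk."""
    cfg = dd.SimConfig(n_dyads=2, n_mixed_dyads=1, events_per_dyad=8,
                       task_duration=220.0, seed=123)
    out = tmp_path / "study"
    dd.simulate_study(cfg, outdir=out)
    return out
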