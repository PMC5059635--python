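import numpy as np
import pytest

import pmfbind as pb


@pytest.fixture(scope="session")
def thermo():
    return pb.ThermoParams()


@pytest.fixture(scope="session")
def flat_potential():
    return pb.preset_potential("flat")


@pytest.fixture(scope="session")
def flat_umbrella_run(flat_potential):
    """Moderate flat-potential umbrella run reused across WHAM tests."""
    windows = pb.make_window_layout(-25.0, -15.0, 0.5, 10.0)
    params = pb.SamplerParams(n_steps=22_000)
    seeds = pb.derive_window_seeds(11, len(windows))
    series = pb.sample_umbrella_windows(flat_potential, windows, params, seeds)
    hists = pb.build_histograms(series, bin_width=0.1)
    return series, hists


def iid_gaussian_series(windows, n, kt, seed):
    """Time series of i.i.d. draws from each window's analytic biased
    Gaussian (flat true potential): mean z0, variance kt/k."""
    rng = np.random.default_rng(seed)
    out = []
    for w in windows:
        sd = np.sqrt(kt / w.force_constant)
        samples = w.centre + sd * rng.standard_normal(n)
        out.append(pb.TimeSeries(samples=samples, window=w, seed=seed))
    return out
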