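import numpy as np
import pytest

from axonatp import (
    Epoch,
    IRFHistogram,
    MultiExpModel,
    ProtocolSpec,
    SimConfig,
    make_bin_times,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def long_window_cfg():
    """Acquisition with a 100 ns window, no wrap and a delta IRF at t=0:
    the regime where the moment estimator is unbiased."""
    return SimConfig(
        seed=0,
        rep_frequency=8.0e6,  # 125 ns period >= window
        bin_width=0.1,
        n_bins=1000,
        irf_center=0.0,
        irf_width_sigma=0.0,
        wrap=False,
    )


@pytest.fixture
def delta_irf(long_window_cfg):
    """Delta IRF in the first bin of the long window."""
    counts = np.zeros(long_window_cfg.n_bins)
    counts[0] = 1.0
    return IRFHistogram(
        bin_times=long_window_cfg.bin_times,
        counts=counts,
        bin_width=long_window_cfg.bin_width,
        rep_frequency=long_window_cfg.rep_frequency,
    )


@pytest.fixture
def mono_model():
    return MultiExpModel(amplitudes=[1.0], lifetimes=[2.0])


@pytest.fixture
def bi_model():
    """The reference bi-exponential: amplitude-weighted mean 2.25 ns."""
    return MultiExpModel(amplitudes=[0.3, 0.7], lifetimes=[0.5, 3.0])


@pytest.fixture
def gd_protocol():
    from axonatp import standard_gd_protocol

    return standard_gd_protocol()


@pytest.fixture
def gd_kinetics():
    return {
        "GD": {"rate_per_s": 1.0 / 400.0, "plateau": 0.05},
        "reperfusion": {"delay_s": 120.0, "tau_s": 200.0, "plateau": 0.6},
        "MBGD": {"ramp_s": 300.0},
    }


def make_histogram(counts, bin_width=0.1, rep_frequency=8.0e6, cls=None):
    """Helper for hand-built histograms."""
    from axonatp import DecayHistogram

    counts = np.asarray(counts)
    cls = cls or DecayHistogram
    return cls(
        bin_times=make_bin_times(counts.size, bin_width),
        counts=counts,
        bin_width=bin_width,
        rep_frequency=rep_frequency,
    )


@pytest.fixture
def hist_factory():
    return make_histogram


@pytest.fixture
def short_protocol():
    """Compressed GD/reperfusion protocol for fast trace tests."""
    return ProtocolSpec([
        Epoch("baseline", 0.0, 300.0),
        Epoch("GD", 300.0, 900.0),
        Epoch("reperfusion", 900.0, 1800.0),
        Epoch("MBGD", 1800.0, 2400.0),
    ])
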