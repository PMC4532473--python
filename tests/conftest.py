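import numpy as np
import pytest

from emgcwt import (
    AnalysisSettings,
    SimulationConfig,
    generate_mvc,
    generate_session,
)
from emgcwt.pipeline import SessionData


@pytest.fixture(scope="session")
def short_config():
    """A 12-cycle session: enough for one 10-cycle block, fast to analyze."""
    return SimulationConfig(n_cycles=12, seed=7)


@pytest.fixture(scope="session")
def short_session(short_config):
    recording, switch, truth = generate_session(short_config)
    return SessionData(
        recording=recording,
        switch=switch,
        mvcs=generate_mvc(short_config),
        load=2.0,
        truth=truth,
        config=short_config,
    )


@pytest.fixture(scope="session")
def settings():
    return AnalysisSettings()


def periodogram_median_freq(x: np.ndarray, fs: float) -> float:
    """Independent median-frequency oracle: periodogram + half-cumulative power."""
    from scipy.integrate import cumulative_trapezoid
    from scipy.signal import periodogram

    f, p = periodogram(x, fs)
    c = cumulative_trapezoid(p, f, initial=0.0)
    return float(np.interp(c[-1] / 2.0, c, f))


def make_cycle_map(power: np.ndarray):
    """Wrap a 496x401 array (or any 2-D array) as a CycleMap on physical axes."""
    from emgcwt import CycleMap

    n_rows, n_cols = power.shape
    return CycleMap(
        power=np.asarray(power, dtype=float),
        frequencies=5.0 + np.arange(n_rows, dtype=float),
        percent=np.linspace(0.0, 100.0, n_cols),
        n_cycles_averaged=1,
    )
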