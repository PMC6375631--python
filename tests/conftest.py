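import numpy as np
import pytest

from polvmut import ExtensionSimParams, FretSimParams, gen_extension_timecourse

STANDARD_TIMES = np.array([0.0, 15, 30, 60, 90, 120, 180, 240, 300])


@pytest.fixture
def standard_times():
    return STANDARD_TIMES.copy()


@pytest.fixture
def noiseless_timecourse():
    """Noiseless extension curve at the 37C ATPgammaS ground truth (k=0.008, D=0.028)."""
    return gen_extension_timecourse(
        ExtensionSimParams(k=0.008, D=0.028, times=STANDARD_TIMES))


@pytest.fixture
def noisy_fret_params():
    """Study-condition trajectory ensemble: tau_bound 6.1 s, tau_unbound 17 s,
    E_bound 0.7, 0.3 s frames, 10% intensity noise."""
    return FretSimParams(tau_bound=6.1, tau_unbound=17.0, E_bound=0.7,
                         frame_dt=0.3, duration=180.0, I_total=300.0,
                         noise_sd=30.0, n_traj=60, seed=11)
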