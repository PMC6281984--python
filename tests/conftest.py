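import numpy as np
import pandas as pd
import pytest

from hybridphase import detector, synth


@pytest.fixture(scope="session")
def default_session():
    """One synthetic session at the default study conditions."""
    return synth.generate_session(synth.SessionSpec(seed=123))


@pytest.fixture(scope="session")
def default_run(default_session):
    """Full hybrid pipeline result on the default session."""
    return detector.run_hybrid_session(default_session)


@pytest.fixture()
def ray_series():
    """Analytic fourth-quadrant ray: hbo = v*t, hbr = -v*t/3.

    The vector magnitude grows linearly, so circle-crossing times have the
    closed form t = 3*r / (v*sqrt(10)).
    """
    from hybridphase.preproc import HemoSeries

    rate, v = 9.19, 3.0e-4
    t = np.arange(int(5 * rate)) / rate
    return HemoSeries(v * t, -v * t / 3.0, rate, channel_id=1), v


def gate_frame(times_end, window_s=1.0):
    """Gate-event table covering the given window-end times."""
    te = np.asarray(times_end, dtype=float)
    return pd.DataFrame(
        {
            "window_id": np.arange(len(te)),
            "t_start": te - window_s,
            "t_end": te,
            "power": np.ones(len(te)),
            "threshold": np.full(len(te), 0.5),
        }
    )
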