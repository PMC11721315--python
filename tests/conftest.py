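import numpy as np
import pandas as pd
import pytest

from ventzone import synthetic, zones


@pytest.fixture(scope="session")
def default_table():
    return zones.load_zone_table("default_v1")


def make_frame(times, spo2=96.0, peep=5.0, fio2=30.0, mode="automated",
               controller="automated", alarm=False, set_peep=6.0, set_fio2=35.0):
    """Canonical breath frame from scalars or parallel sequences."""
    n = len(times)

    def col(v):
        return np.full(n, v) if np.isscalar(v) or isinstance(v, str) else np.asarray(v)

    return pd.DataFrame({
        "time": np.asarray(times, float), "spo2": col(spo2), "peep": col(peep),
        "fio2": col(fio2), "mode": col(mode), "controller": col(controller),
        "alarm": col(alarm).astype(bool), "set_peep": col(set_peep),
        "set_fio2": col(set_fio2),
    })


@pytest.fixture(scope="session")
def small_cohort():
    """4 patients, 30 min phases: fast but exercises every pipeline stage."""
    config = synthetic.SyntheticConfig(
        n_patients=4, phase_minutes=30.0, washout_minutes=10.0, seed=11)
    return synthetic.generate_cohort(config)
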