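import numpy as np
import pytest

from spectqc import contrast as con
from spectqc import phantom_sim as sim


def spheres_from_truth(truth):
    return [
        con.SphereSpec(tuple(np.asarray(c, dtype=float)), float(d), bool(h))
        for c, d, h in zip(truth["sphere_centers_mm"],
                           truth["sphere_diameters_mm"],
                           truth["hot_flags"])
    ]


@pytest.fixture(scope="session")
def iec_noiseless():
    """Noiseless, unblurred IEC phantom at the 8:1 fill ratio."""
    vol, truth = sim.gen_iec_volume(sphere_to_background_ratio=8.0,
                                    noiseless=True)
    return vol, truth


@pytest.fixture(scope="session")
def saturating_series():
    """Noiseless decay-source series through the plateau-matched
    saturating response (plateau 760 kcps, 20 % loss at 917 kcps)."""
    k = sim.solve_saturating_shape(760e3, 917e3, 0.2)
    resp = sim.ResponseModel("saturating_exponential",
                             {"ocr_max": 760e3, "k": k})
    from spectqc.datatypes import T_HALF_TC99M_S
    sched = sim.decay_schedule(11 * T_HALF_TC99M_S, T_HALF_TC99M_S)
    series, truth = sim.gen_decay_series(
        3000.0, T_HALF_TC99M_S, resp, cps_per_MBq=1000.0,
        schedule=sched, noiseless=True)
    return series, truth
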