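"""Shared builders for the dSTORM-chain tests."""

import numpy as np
import pytest

from pullstorm.synthetic import (
    AcquisitionParams,
    BlinkParams,
    make_disc,
    simulate_storm_table,
)


def dense_drift_scene(seed: int, drift=(0.0, 0.0), n_frames: int = 4000):
    """Dense localization scene for drift estimation: a 7×7 grid of bright
    discs on a 97-pixel field, ~40k localizations."""
    acq = AcquisitionParams(fov_side=97, n_frames_storm=n_frames)
    rng = np.random.default_rng(seed)
    side = acq.fov_side_nm
    truths = []
    for i in range(7):
        for j in range(7):
            c = (1200 + i * (side - 2400) / 6 + rng.normal(0, 50),
                 1200 + j * (side - 2400) / 6 + rng.normal(0, 50))
            truths.append(make_disc(c, 0.02, rng, emitter_density=1 / 50.0))
    blink = BlinkParams(mean_bursts=4.0)
    table, _ = simulate_storm_table(truths, acq, drift=drift, blink=blink,
                                    seed=seed)
    return table, acq


@pytest.fixture(scope="session")
def ramp_scene():
    """100 nm linear drift ramp over the acquisition."""
    n_frames = 4000
    rate = 100.0 / (n_frames - 1)
    table, acq = dense_drift_scene(seed=11, drift=(rate, 0.0), n_frames=n_frames)
    return table, acq, rate
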