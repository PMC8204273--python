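import numpy as np
import pytest
from hypothesis import settings

import msirepi as m

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def brain_phantom():
    """Small two-tissue brain phantom shared across tests."""
    return m.make_brain_phantom(grid_shape=(24, 24, 8), seed=1)


@pytest.fixture(scope="session")
def protocol_8ti():
    """8-slice, 8-acquisition protocol (one TI per slot offset)."""
    return m.AcquisitionProtocol(
        tr_ms=5000.0, n_slices=8, sms_factor=1,
        slice_offsets=tuple(range(8)), min_ti_ms=44.5,
    )


@pytest.fixture(scope="session")
def fa_sweep_r1_maps(brain_phantom, protocol_8ti):
    """Noiseless fitted R1 maps across the fat-suppression flip-angle sweep.

    Returns (fa_list, r1_maps, valid_mask): the full simulate -> polarity ->
    fit -> 1000/T1 chain per flip angle.
    """
    fas = [0.0, 30.0, 40.0, 50.0, 60.0, 70.0]
    maps = []
    valid = None
    for fa in fas:
        proto = m.AcquisitionProtocol(
            tr_ms=5000.0, n_slices=8, sms_factor=1,
            slice_offsets=tuple(range(8)), min_ti_ms=44.5,
            fs_flip_angle_deg=fa,
        )
        series = m.simulate_series(brain_phantom, proto, snr=None)
        fit = m.fit_t1_volume(series)
        r1 = np.where(fit.valid, 1000.0 / fit.t1_ms, np.nan)
        maps.append(r1)
        valid = fit.valid if valid is None else (valid & fit.valid)
    return fas, maps, valid & brain_phantom.support
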