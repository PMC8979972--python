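import numpy as np
import pytest

import respsort as rs

# ROIs matching the default phantom layout
RESP_ROI = rs.RespROI(72, 112, 12, 52)
LV_ROI = rs.RespROI(14, 72, 36, 92)


@pytest.fixture(scope="session")
def phantom_slice():
    """Single phantom slice: 500 frames, period 90, plateau 0.3, 20 dB SNR."""
    resp = rs.RespWaveformParams(period_frames=90, amplitude_px=8,
                                 plateau_asymmetry=0.3, phase_offset=0.0)
    series, truth = rs.generate_cine_slice(
        resp=resp, n_frames=500, noise_sd=rs.noise_sd_from_snr(20.0), seed=1)
    return series, truth


@pytest.fixture(scope="session")
def phantom_stack():
    """Seeded 8-slice stack, 500 frames per slice, 20 dB SNR."""
    return rs.generate_cine_stack(n_slices=8, n_frames=500,
                                  noise_sd=rs.noise_sd_from_snr(20.0), seed=1)


@pytest.fixture(scope="session")
def sorted_run(phantom_stack):
    """Full pipeline run at end expiration on the session stack."""
    stack, truth = phantom_stack
    sorted_stack, diags = rs.sort_stack(stack, RESP_ROI, LV_ROI, mode="rest",
                                        states=(rs.EXPIRATION,))
    selections = [s for d in diags for s in d.selections]
    masks = rs.masks_from_truth(truth.slices, selections)
    result = rs.quantify_states(sorted_stack, masks)[rs.EXPIRATION]
    return dict(stack=stack, truth=truth, sorted_stack=sorted_stack,
                diags=diags, selections=selections, masks=masks, result=result)


@pytest.fixture(scope="session")
def noise_free_slice():
    series, truth = rs.generate_cine_slice(n_frames=500, noise_sd=0.0, seed=3)
    return series, truth
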