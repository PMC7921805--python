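import numpy as np
import pytest

from kchtow.gillespie import SampledTrack
from kchtow.motor_model import MotorTeamParams, TugOfWarParams, default_params


@pytest.fixture(scope="session")
def params() -> TugOfWarParams:
    return default_params()


@pytest.fixture
def example_team() -> MotorTeamParams:
    """Team whose superstall backslip is one tenth of the fast forward speed;
    used for hand-evaluated force-balance examples."""
    return MotorTeamParams(
        stall_force_pN=3.0,
        detachment_force_pN=10.0,
        binding_rate_per_s=0.6,
        unbinding_rate_per_s=1.6,
        forward_speed_um_s=0.08,
        backslip_speed_um_s=0.008,
    )


def track_from_positions(positions_um, dt=5.0, track_id="t"):
    positions_um = np.asarray(positions_um, dtype=float)
    return SampledTrack(
        track_id=track_id,
        frame_interval_s=dt,
        times_s=dt * np.arange(len(positions_um)),
        positions_um=positions_um,
        provenance="synthetic",
    )


def track_from_velocities(v_nm_s, dt=5.0, track_id="t"):
    """Track whose consecutive interval velocities equal v_nm_s exactly."""
    v = np.asarray(v_nm_s, dtype=float)
    x = np.concatenate([[0.0], np.cumsum(v * dt / 1000.0)])
    return track_from_positions(x, dt=dt, track_id=track_id)
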