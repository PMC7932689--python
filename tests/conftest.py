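import numpy as np
import pytest

from arslip.step_kinematics import step_geometry, tripod_step_windows
from arslip.synthetic import SyntheticConfig, generate_fly_dataset

W1118_MASS = 1.123e-6   # kg
W1118_R = 2.042e-3      # m


def eligible_windows(ds, min_frames: int = 8):
    """Tripod-stance records with geometry filled in, restricted to windows
    the CoM recording actually covers."""
    records = tripod_step_windows(ds.footfalls)
    out = []
    for rec in records:
        n = np.sum((ds.com.t >= rec.window[0]) & (ds.com.t <= rec.window[1]))
        if n < min_frames:
            continue
        rec.fly_id = ds.config.fly_id
        step_geometry(rec, ds.footfalls, ds.com)
        out.append(rec)
    return out


def matching_truth(ds, rec):
    """Ground-truth record of the generated step closest to a window."""
    return min(ds.truth["steps"],
               key=lambda s: abs(s["window"][0] - rec.window[0]))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless synthetic walking bout (shared, read-only)."""
    return generate_fly_dataset(
        SyntheticConfig(n_steps=10, seed=42, sigma_z=0.0, sigma_x=0.0))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Synthetic bout at the study's default measurement noise."""
    return generate_fly_dataset(SyntheticConfig(n_steps=10, seed=42))
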