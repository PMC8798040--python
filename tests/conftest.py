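"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import volgrowth as vg


def synthetic_annotation(cell_ids, t_birth=0.0, t_g1s=100.0, t_mitosis=np.nan,
                         birth_volume=2000.0) -> pd.DataFrame:
    """Minimal annotation table for hand-built trajectory fixtures."""
    return pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "parent_id": None,
            "t_birth": t_birth,
            "t_g1s": t_g1s,
            "t_mitosis": t_mitosis,
            "overshoot_start": np.nan,
            "overshoot_end": np.nan,
            "birth_volume": birth_volume,
        }
    )


def trajectories_from_array(volumes: np.ndarray, frame_interval: float = 1 / 6
                            ) -> pd.DataFrame:
    """One-cell trajectory table from a volume array."""
    n = len(volumes)
    return pd.DataFrame(
        {
            "cell_id": "c0000",
            "frame": np.arange(n),
            "time_h": np.arange(n) * frame_interval,
            "volume_um3": np.asarray(volumes, dtype=float),
            "valid": True,
        }
    )


@pytest.fixture(scope="session")
def small_population():
    """Additive-noise population with the default cell-cycle structure."""
    params = vg.GrowthModelParams(alpha_g1=0.042, alpha_sg2=0.042, sigma=85.0,
                                  gamma=0.0, seed=101)
    traj, ann, info = vg.simulate_population(params, 80, 24.0)
    return params, traj, ann, info


@pytest.fixture(scope="session")
def small_dataset(small_population):
    params, traj, ann, _ = small_population
    return vg.make_dataset(traj, ann, params.frame_interval)


@pytest.fixture(scope="session")
def small_clean(small_dataset):
    clean, report = vg.preprocess_dataset(small_dataset)
    return clean, report
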