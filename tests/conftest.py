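import numpy as np
import pandas as pd
import pytest

from metabotrend import Dataset, SimulationSpec, simulate_timecourse


def make_dataset(values, groups, times, batches=None, acq=None, replicates=None):
    """Small hand-built Dataset; values is (n_obs, n_peaks) array-like."""
    values = np.asarray(values, dtype=float)
    n_obs, n_peaks = values.shape
    obs_ids = [f"O{i}" for i in range(n_obs)]
    peak_ids = [f"P{i}" for i in range(n_peaks)]
    obs = pd.DataFrame(
        {
            "group": groups,
            "time": times,
            "batch": batches if batches is not None else ["B1"] * n_obs,
            "acq_order": acq if acq is not None else list(range(1, n_obs + 1)),
            "replicate": replicates if replicates is not None else ["r1"] * n_obs,
        },
        index=pd.Index(obs_ids, name="obs_id"),
    )
    peaks = pd.DataFrame(
        {"mz": np.linspace(100, 500, n_peaks), "rt": 60.0, "mode": "+"},
        index=pd.Index(peak_ids, name="peak_id"),
    )
    return Dataset(
        values=pd.DataFrame(values, index=obs.index, columns=peak_ids),
        obs=obs,
        peaks=peaks,
    )


@pytest.fixture(scope="session")
def small_study():
    """20-peak, 4-group simulated study with QCs and two offset batches."""
    spec = SimulationSpec(n_peaks=20, batch_offsets=(0.0, 5.0), noise_sd=0.5, seed=42)
    ds, kb, truth = simulate_timecourse(spec)
    return ds, kb, truth
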