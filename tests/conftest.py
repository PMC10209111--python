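import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from layerphys.datatypes import AlignedResponses
from layerphys.spikes import WindowSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def make_aligned(response_trials, baseline_trials=None, window=None,
                 unit_id="u0", condition="L"):
    """Build AlignedResponses from lists of relative spike-time arrays."""
    window = window or WindowSpec()
    response = [np.asarray(t, dtype=float) for t in response_trials]
    if baseline_trials is None:
        baseline_trials = [[] for _ in response]
    baseline = [np.asarray(t, dtype=float) for t in baseline_trials]
    return AlignedResponses(unit_id, condition, baseline, response, window)


@pytest.fixture
def phy_dir(tmp_path):
    """A minimal Phy-style sorted-spike directory: 3 clusters, one noise."""
    rate = 30030.0
    # cluster 0: good, spikes at 1.0 s and 2.0 s; cluster 1: noise;
    # cluster 2: good, one spike at 0.5 s
    samples = np.array([30030, 2 * 30030, 1000, int(0.5 * 30030)], dtype=np.int64)
    clusters = np.array([0, 0, 1, 2], dtype=np.int32)
    np.save(tmp_path / "spike_times.npy", samples)
    np.save(tmp_path / "spike_clusters.npy", clusters)
    info = pd.DataFrame(
        {
            "unit_id": [0, 1, 2],
            "group": ["good", "noise", "good"],
            "depth_um": [1205.0, 300.0, 589.0],
            "channel": [12, 3, 40],
            "trough_peak_us": [400.0, 150.0, 210.0],
        }
    )
    info.to_csv(tmp_path / "cluster_info.tsv", sep="\t", index=False)
    return tmp_path, rate
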