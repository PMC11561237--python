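import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import swextract as sw

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def cubic_box():
    return sw.PeriodicBox.cubic(10.0)


@pytest.fixture
def small_trajectory(cubic_box):
    """Two frames, three particles of two species, coordinates at 6-decimal grid."""
    rng = np.random.default_rng(1234)
    species = ("O_water", "H_water", "O_OHcurcumin")
    frames = []
    for k in range(2):
        coords = np.round(rng.uniform(0, 10, size=(3, 3)), 6)
        frames.append(
            sw.Frame(time=float(k) * 10.0, species=species, coordinates=coords, wrapped=True)
        )
    return sw.Trajectory(box=cubic_box, frames=frames, timestep=10.0)


def brute_force_pair_counts(coords_a, coords_b, box, bin_edges, same_species):
    """O(N²) reference: explicit double loop with per-component minimum image."""
    lengths = box.lengths
    counts = np.zeros(len(bin_edges) - 1)
    n_a = len(coords_a)
    n_b = len(coords_b)
    for i in range(n_a):
        j_start = i + 1 if same_species else 0
        for j in range(j_start, n_b):
            d = coords_a[i] - coords_b[j]
            d = d - lengths * np.round(d / lengths)
            r = float(np.sqrt(np.sum(d * d)))
            for b in range(len(bin_edges) - 1):
                if bin_edges[b] <= r < bin_edges[b + 1]:
                    counts[b] += 1
                    break
    return counts
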