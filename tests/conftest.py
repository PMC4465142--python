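import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150410)


@pytest.fixture
def linear_cumulative():
    """Cumulative DVH falling linearly from (0 Gy, 1) to (50 Gy, 0)."""
    from gatedose import CumulativeDVH
    dose = np.linspace(0.0, 50.0, 1001)
    return CumulativeDVH(dose=dose,
                         volume_fraction_at_or_above=1.0 - dose / 50.0)


def random_differential_dvh(rng, n_bins=200, bin_width=0.05, max_start=20.0):
    """Random normalized differential DVH on a uniform grid."""
    from gatedose import DifferentialDVH
    start = rng.uniform(0.0, max_start)
    start = max(start, bin_width / 2.0)
    centers = start + bin_width * np.arange(n_bins)
    fracs = rng.random(n_bins)
    fracs /= fracs.sum()
    return DifferentialDVH(bin_center=centers, volume_fraction=fracs,
                           bin_width=bin_width)
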