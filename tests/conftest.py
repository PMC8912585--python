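import numpy as np
import pytest

from evipheno.series import EviSeries, composite_dates
from evipheno.synthetic import (
    ClimateConfig,
    CouplingConfig,
    CurveConfig,
    gen_coupled_dataset,
)


def make_series(values, start_year=2000, site="test", pixel="px0"):
    """EviSeries on the full composite calendar from a flat value array."""
    values = np.asarray(values, dtype=float)
    assert len(values) % 46 == 0
    dates = composite_dates(start_year, len(values) // 46)
    return EviSeries(site, pixel, dates, values)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """5-year coupled dataset with no observation or event noise."""
    curve = CurveConfig(noise_sd=0.0, dropout_prob=0.0)
    coupling = CouplingConfig(event_noise_sd={e: 0.0 for e in ("sdo", "sde", "aro", "are")})
    return gen_coupled_dataset(curve, ClimateConfig(), coupling, n_years=5)


@pytest.fixture(scope="session")
def noisy_dataset():
    """21-year dataset under the study's stated noise conditions.

    Observation noise SD 0.01, 10% cloud dropouts, 4-day event-timing noise.
    """
    curve = CurveConfig(noise_sd=0.01, dropout_prob=0.1, seed=7)
    return gen_coupled_dataset(curve, ClimateConfig(seed=8), CouplingConfig(seed=9),
                               n_years=21)
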