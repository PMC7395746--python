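import numpy as np
import pytest

from methylex.exchange import CPMGSchedule, ExchangeParams, SiteParams
from methylex.synthetic import SyntheticScenario, gen_dispersion_dataset


@pytest.fixture
def schedule_800():
    """Standard 30 ms constant-time schedule at 800 MHz."""
    return CPMGSchedule(0.030, (66.7, 133.3, 200.0, 333.3, 533.3, 1000.0), 800.0)


@pytest.fixture
def free_enzyme_params():
    """Free-enzyme-like global exchange with one Ile reporter."""
    return ExchangeParams(
        1950.0, 0.03, {"I56": SiteParams(1.0, 0.0, {600.0: 20.0, 800.0: 20.0})}
    )


def make_scenario(kex, seed, n_sites=6, pm=0.03, noise=0.02,
                  fields=(600.0, 800.0), dwc_range=(0.3, 1.5), dwh=None):
    """Dispersion scenario with per-site dwC drawn uniformly from a range."""
    rng = np.random.default_rng(seed)
    sites = {}
    for i, dw in enumerate(rng.uniform(*dwc_range, n_sites)):
        name = f"I{i + 1}"
        sites[name] = SiteParams(
            float(dw), (dwh or {}).get(name, 0.0), {f: 20.0 for f in fields}
        )
    truth = ExchangeParams(kex, pm, sites)
    return SyntheticScenario(
        seed=seed, truth=truth, fields_mhz=tuple(fields), intensity_noise=noise
    )


@pytest.fixture
def noisy_datasets():
    """6-site, 2-field, 2 % noise dataset at the free-enzyme exchange rate."""
    scn = make_scenario(1950.0, seed=7)
    datasets, raw = gen_dispersion_dataset(scn)
    return scn, datasets, raw
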