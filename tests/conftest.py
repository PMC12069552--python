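import pytest

from scncomplex.calibration import WT_AFFINITIES, calibrate_all
from scncomplex.niche import simulate_niche
from scncomplex.scenarios import delta_prd_affinities
from scncomplex.synthetic import DEFAULT_ABUNDANCE_MEANS


@pytest.fixture(scope="session")
def wt_rates():
    rates, scans = calibrate_all(WT_AFFINITIES, seed=1)
    return rates, scans


@pytest.fixture(scope="session")
def dprd_rates():
    rates, _ = calibrate_all(delta_prd_affinities(), seed=1)
    return rates


@pytest.fixture(scope="session")
def wt_signatures(wt_rates):
    rates, _ = wt_rates
    return simulate_niche(DEFAULT_ABUNDANCE_MEANS, rates)


@pytest.fixture(scope="session")
def dprd_signatures(dprd_rates):
    return simulate_niche(DEFAULT_ABUNDANCE_MEANS, dprd_rates)
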