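import numpy as np
import pytest

from acoustica import (
    SiteScenario,
    apply_exclusion_layers,
    filter_seds,
    integrate_transects,
    simulate_transect,
    threshold_sv,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def shallow_scenario():
    """Mid-density shallow site used by recovery tests (footprint ~0.15 ha)."""
    return SiteScenario(
        site_id="X",
        habitat="mixed",
        true_areal_density=500.0,
        length_meanlog=float(np.log(12.0)),
        length_sdlog=0.3,
        depth_range_m=(20.0, 30.0),
        n_transects=1,
    )


def analyze_transect(pings, seds):
    """Run the standard processing chain on one simulated transect."""
    pings = threshold_sv(pings)
    pings, seds = apply_exclusion_layers(pings, seds)
    accepted, _ = filter_seds(seds)
    return integrate_transects(pings, accepted)[0]
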