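import itertools

import pytest

from metanet import (
    MetastaticState,
    RateParameters,
    SiteNetwork,
    enumerate_reachable_states,
    load_network,
    stage_to_time,
)

#: Published linear-map estimates for the four-station tongue network,
#: used as a realistic operating point for synthetic cohorts.
TONGUE_THETA = {
    "lambda_I": 0.09,
    "lambda_II": 0.19,
    "lambda_III": 0.04,
    "phi_I": 0.09,
    "phi_II": 0.21,
    "phi_III": 0.07,
}

#: Published estimates for the five-site ovarian network.
OVARIAN_THETA = {
    "lambda_1": 0.046,
    "lambda_2": 0.004,
    "phi_1": 0.007,
    "phi_2": 0.092,
    "phi_3": 0.015,
    "phi_4": 0.004,
}


@pytest.fixture(scope="session")
def tongue_net():
    return load_network("tongue")


@pytest.fixture(scope="session")
def tongue_space(tongue_net):
    return enumerate_reachable_states(tongue_net)


@pytest.fixture(scope="session")
def ovarian_net():
    return load_network("ovarian")


@pytest.fixture(scope="session")
def ovarian_space(ovarian_net):
    return enumerate_reachable_states(ovarian_net)


@pytest.fixture(scope="session")
def tongue_theta():
    return RateParameters(TONGUE_THETA)


@pytest.fixture(scope="session")
def ovarian_theta():
    return RateParameters(OVARIAN_THETA)


@pytest.fixture(scope="session")
def tongue_stages():
    return ("T1", "T2", "T3", "T4")


@pytest.fixture(scope="session")
def linear_map(tongue_stages):
    return stage_to_time("linear", tongue_stages)


@pytest.fixture(scope="session")
def chain2_net():
    """Two-site chain: primary -> A (lam), A -> B (phi)."""
    return SiteNetwork(
        sites=("A", "B"),
        primary_edges={"A": "lam"},
        secondary_edges={("A", "B"): "phi"},
    )


@pytest.fixture(scope="session")
def single_site_net():
    return SiteNetwork(sites=("A",), primary_edges={"A": "lam"}, secondary_edges={})


def brute_force_reachable(net: SiteNetwork) -> set[str]:
    """Independent reachability oracle: test every binary vector.

    A state is attainable iff its positive set can be built by repeatedly
    adding a site with a primary edge or an already-added feeder.
    """
    reachable = set()
    for bits in itertools.product((0, 1), repeat=net.n_sites):
        target = {net.sites[v] for v, b in enumerate(bits) if b}
        added: set[str] = set()
        grown = True
        while grown:
            grown = False
            for site in sorted(target - added):
                has_feed = site in net.primary_edges or any(
                    u in added for u in net.feeders_of(site)
                )
                if has_feed:
                    added.add(site)
                    grown = True
        if added == target:
            reachable.add(str(MetastaticState(bits)))
    return reachable
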