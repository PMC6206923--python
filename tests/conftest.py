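"""Shared fixtures: the two-region synthetic demo, generated once."""

from __future__ import annotations

import pytest

from gcea.pipeline import analyse_region
from gcea.synthetic import generate_region_params, make_two_region_demo


@pytest.fixture(scope="session")
def demo_profiles():
    return make_two_region_demo()


@pytest.fixture(scope="session")
def sea_bundle(demo_profiles):
    return generate_region_params(demo_profiles[0])


@pytest.fixture(scope="session")
def essa_bundle(demo_profiles):
    return generate_region_params(demo_profiles[1])


@pytest.fixture(scope="session")
def sea_report(sea_bundle):
    return analyse_region(sea_bundle)


@pytest.fixture(scope="session")
def essa_report(essa_bundle):
    return analyse_region(essa_bundle)
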