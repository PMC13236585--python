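"""Shared fixtures: one synthetic family set, calibrated once per session."""

from __future__ import annotations

import pytest

from cazprofiler.calibration import calibrate_families
from cazprofiler.substrate_scheme import example_scheme_path, load_scheme
from cazprofiler.synthetic_fixtures import (
    FixtureSpec,
    make_catalogue_and_reads,
    make_families,
    make_genome_collection,
)

SEED = 1


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(seed=SEED)


@pytest.fixture(scope="session")
def family_fixture(fixture_spec):
    return make_families(fixture_spec)


@pytest.fixture(scope="session")
def calibrated_models(family_fixture):
    return calibrate_families(
        family_fixture.families, family_fixture.negative_pool, seed=SEED
    )


@pytest.fixture(scope="session")
def catalogue_fixture(fixture_spec, family_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("catalogue")
    return make_catalogue_and_reads(fixture_spec, family_fixture, outdir)


@pytest.fixture(scope="session")
def genome_collection(fixture_spec):
    return make_genome_collection(fixture_spec)


@pytest.fixture(scope="session")
def scheme():
    return load_scheme(example_scheme_path())
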