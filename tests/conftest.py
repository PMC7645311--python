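import dataclasses

import pytest

from piglca.synthetic import (default_fixtures, default_line_specs,
                              generate_cohort, mean_pig)


@pytest.fixture(scope="session")
def fx():
    return default_fixtures()


@pytest.fixture(scope="session")
def line_specs():
    lrfi, hrfi = default_line_specs()
    return {"LRFI": lrfi, "HRFI": hrfi}


@pytest.fixture(scope="session")
def small_specs(line_specs):
    """Down-sized line specs (n=12) for fast cohort-level tests."""
    return {k: dataclasses.replace(v, n=12) for k, v in line_specs.items()}


@pytest.fixture(scope="session")
def small_cohort(small_specs, fx):
    pigs = []
    for spec in small_specs.values():
        pigs.extend(generate_cohort(spec, seed=11, diet=fx.diet, cfg=fx.config))
    return pigs


@pytest.fixture(scope="session")
def mean_pigs(line_specs, fx):
    return {label: mean_pig(spec, fx.diet, cfg=fx.config)
            for label, spec in line_specs.items()}
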