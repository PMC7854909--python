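import numpy as np
import pandas as pd
import pytest

from nbstiming.simulate import (
    GeneratorConfig,
    MetaboliteSpec,
    default_config,
    generate_cohort,
)


def flat_spec(name="M", base=10.0, cv=0.25, shifts=None):
    """A constant-trajectory analyte: the null condition for effect sizes."""
    return MetaboliteSpec(name=name, shape="constant", base=base, cv=cv,
                          shifts=shifts or {})


def flat_config(n=10_000, seed=0, specs=None, aabc_weights=None):
    """Cohort config with flat trajectories and no covariate shifts."""
    if aabc_weights is None:
        hours = list(range(12, 49))
        aabc_weights = {h: 1.0 / len(hours) for h in hours}
    return GeneratorConfig(
        n_newborns=n,
        seed=seed,
        aabc_weights=aabc_weights,
        metabolites=tuple(specs or [flat_spec()]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 5,000-record default synthetic cohort shared across tests."""
    return generate_cohort(default_config(5_000, seed=11))


@pytest.fixture()
def exclusion_fixture():
    """Six hand-built records: one violation per rule plus one clean record."""
    base = dict(ga=39, bw=3200, sex="female", race_reported="White",
                tpn="no", screen="negative", Phe=50.0)
    rows = [
        dict(base, id="r1", aabc=11),       # collected too early
        dict(base, id="r2", aabc=200),      # collected too late
        dict(base, id="r3", aabc=30, bw=900),   # birth weight below range
        dict(base, id="r4", aabc=30, ga=27),    # gestational age below range
        dict(base, id="r5", aabc=30, tpn="unknown"),
        dict(base, id="r6", aabc=30),       # clean
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
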