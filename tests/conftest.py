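import dataclasses

import pytest

from allovot.cohort import default_cohort_spec, simulate_cohort
from allovot.io import aggregate_discrim
from allovot.sdt import build_curves


@pytest.fixture(scope="session")
def full_cohort():
    """Default study-sized cohort (204 subjects), seed 1."""
    spec = default_cohort_spec(seed=1)
    ident, discrim, truth = simulate_cohort(spec)
    return spec, ident, discrim, truth


@pytest.fixture(scope="session")
def full_curves(full_cohort):
    _, _, discrim, _ = full_cohort
    return build_curves(aggregate_discrim(discrim))


@pytest.fixture(scope="session")
def tiny_spec():
    """Ten-subject cohort for fast structural tests."""
    return default_cohort_spec(
        seed=7,
        n_per_cell={("NR", 2): 3, ("DYS", 2): 3, ("NR", 4): 2, ("DYS", 4): 2},
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return simulate_cohort(tiny_spec)


def one_continuum_spec(seed, n_nr, n_dys, **kw):
    """Cohort spec restricted to ba_pa for oscillator-focused tests."""
    return dataclasses.replace(
        default_cohort_spec(seed=seed, **kw),
        continua=("ba_pa",),
        n_per_cell={("NR", 2): n_nr, ("DYS", 2): n_dys},
    )
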