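"""Shared fixtures: bases, small synthetic datasets, and fitted models.

Expensive fits are session-scoped so several tests can interrogate the same
FitResult.
"""

import numpy as np
import pandas as pd
import pytest

from codalmm.data import compute_olr, stack
from codalmm.model import ModelSpec
from codalmm.fit import fit_cmrlmm
from codalmm.simplex import close
from codalmm.simulate import alt_basis, loh_basis, loh_params, make_fixture, simulate

PARTS = ["sleep", "SB", "LPA", "MVPA"]


@pytest.fixture(scope="session")
def paper_basis():
    return loh_basis()


@pytest.fixture(scope="session")
def other_basis():
    return alt_basis()


@pytest.fixture(scope="session")
def tiny_table():
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def tiny_stacked(tiny_table, paper_basis):
    return stack(compute_olr(tiny_table, paper_basis))


@pytest.fixture(scope="session")
def tiny_spec(paper_basis):
    return ModelSpec(basis=paper_basis)


@pytest.fixture(scope="session")
def loh_table():
    return make_fixture("loh_like", seed=20)


@pytest.fixture(scope="session")
def loh_spec(paper_basis):
    return ModelSpec(
        basis=paper_basis,
        covariates=("zBMI", "income"),
        categorical_levels={"income": ("middle", "high", "low")},
    )


@pytest.fixture(scope="session")
def loh_fit(loh_table, loh_spec, paper_basis):
    stacked = stack(compute_olr(loh_table, paper_basis))
    return fit_cmrlmm(stacked, loh_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_composition(rng, D=4, kappa=1.0):
    return close(rng.lognormal(size=D), kappa, labels=[f"x{i+1}" for i in range(D)])
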