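import numpy as np
import pytest
import sympy as sp

from linident import builtin_example, fix_params


@pytest.fixture(scope="session")
def ex1():
    return builtin_example(1)


@pytest.fixture(scope="session")
def ex1_rates(ex1):
    """Two-compartment model with the known volume V held at 1."""
    model, conds, tv = ex1
    return fix_params(model, {"V": 1}), conds, tv


@pytest.fixture(scope="session")
def ex2():
    return builtin_example(2)


@pytest.fixture(scope="session")
def ex3():
    return builtin_example(3)


@pytest.fixture(scope="session")
def ex4():
    return builtin_example(4)


@pytest.fixture(scope="session")
def insulin_y1():
    return builtin_example(5)


def symbols(*names):
    return sp.symbols(names)


@pytest.fixture
def rng():
    return np.random.default_rng(20151214)
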