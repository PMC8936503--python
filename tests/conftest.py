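import pytest

from fsfn import builtin_generator, compute_descriptors


@pytest.fixture(scope="session")
def gen_a():
    return builtin_generator("A")


@pytest.fixture(scope="session")
def gen_b():
    return builtin_generator("B")


@pytest.fixture(scope="session")
def gen_c():
    return builtin_generator("C")


@pytest.fixture(scope="session")
def desc_a(gen_a):
    return compute_descriptors(gen_a)


@pytest.fixture(scope="session")
def desc_b(gen_b):
    return compute_descriptors(gen_b)


@pytest.fixture(scope="session")
def desc_c(gen_c):
    return compute_descriptors(gen_c)
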