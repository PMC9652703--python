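import numpy as np
import pytest

from dxmeta import (
    fit_bivariate,
    load_packaged_table,
    reconstruct_all,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def records():
    return load_packaged_table()


@pytest.fixture(scope="session")
def tables(records):
    return reconstruct_all(records)


@pytest.fixture(scope="session")
def full_fit(tables):
    """Bivariate fit of the packaged 54-row table (exact-binomial ML)."""
    fit = fit_bivariate(tables)
    assert fit.converged
    return fit
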