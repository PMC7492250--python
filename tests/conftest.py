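import numpy as np
import pytest

from ipcrseq.simulate import ErrorModel, simulate_run


@pytest.fixture(scope="session")
def small_run():
    """A small but complete simulated run shared across module tests.

    Scaled down from the default study conditions (short locus, few
    molecules, few reads) so unit tests stay fast; the full-scale geometry
    is exercised by the end-to-end tests.
    """
    return simulate_run(
        seed=42,
        flank5_len=1200,
        transgene_len=2500,
        flank3_len=1200,
        p35s_offset=1000,
        p35s_len=350,
        background_len=20000,
        n_molecules=4000,
        frag_mean=2500.0,
        frag_sd=250.0,
        model=ErrorModel(mean_read_len=900.0, read_len_sd=400.0),
        n_reads=600,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
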