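import numpy as np
import pytest

from tandemlocus.repeats import ComponentReference
from tandemlocus.synth import (
    ArrayConfig,
    ReadSimConfig,
    build_tandem_bac,
    simulate_reads,
)

# A small-but-complete tandem BAC used across modules: 4 units of 2 kb with a
# skin-style and a liver-style gene cassette each, plus vector and flanks.
SMALL_CFG = dict(
    n_units=4, unit_len=2_000, flank_left_len=600, flank_right_len=600,
    vector_len=800, per_unit_snv_rate=0.003, seed=3,
)


@pytest.fixture(scope="session")
def small_bac():
    return build_tandem_bac(ArrayConfig(**SMALL_CFG))


@pytest.fixture(scope="session")
def small_ref(small_bac):
    locus, truth = small_bac
    return ComponentReference.from_locus(locus, truth)


@pytest.fixture(scope="session")
def small_reads(small_bac):
    locus, _ = small_bac
    cfg = ReadSimConfig(n_reads=300, mean_len=3_000, sd_len=700,
                        min_len=1_000, seed=11)
    return simulate_reads(locus, cfg)


@pytest.fixture(scope="session")
def clean_reads(small_bac):
    """Error-free reads for truth-exactness checks."""
    locus, _ = small_bac
    cfg = ReadSimConfig(n_reads=120, mean_len=3_000, sd_len=700,
                        min_len=1_000, sub_rate=0.0, ins_rate=0.0,
                        del_rate=0.0, seed=13)
    return simulate_reads(locus, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
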