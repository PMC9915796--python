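import numpy as np
import pytest

from mrbee import SimulationConfig, simulate_study
from mrbee.io import VariantRecord


def make_record(variant_id="rs1", ea="A", oa="G", effect=0.1, se=0.01,
                chrom="1", pos=1000, n=10_000, p=None, af=0.3):
    return VariantRecord(
        variant_id=variant_id, effect_allele=ea, other_allele=oa,
        effect=effect, standard_error=se, chromosome=chrom, position=pos,
        sample_size=n, p_value=p, allele_frequency=af,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def null_study():
    """Moderate-size study with no pleiotropy, full overlap, p=2."""
    config = SimulationConfig(m=400, p=2, theta_true=[0.5, 0.5], seed=7)
    return simulate_study(config)


@pytest.fixture(scope="session")
def uni_study():
    """Single-exposure study at the reference settings, smaller m."""
    config = SimulationConfig(m=500, p=1, theta_true=0.5, seed=21)
    return simulate_study(config)
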