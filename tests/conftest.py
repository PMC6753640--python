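import numpy as np
import pytest

from ori_panscan.synthetic_data import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A fast panel for unit-level end-to-end checks."""
    return generate_panel(
        PanelConfig(seed=11, n_chromosomes=3, chrom_length_bp=80_000,
                    n_ars_per_chrom=4, n_strains=8, n_duplicated_ars=1)
    )


@pytest.fixture(scope="session")
def study_panel():
    """The default study conditions: 40 origins, 50 strains, subtelomeric
    deletion bias 0.5 vs 0.02."""
    return generate_panel(PanelConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
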