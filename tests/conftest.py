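import numpy as np
import pytest

from stemtrack import synthetic as stsynth


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured cohort: 2 patients, 80 cells, 400 genes."""
    return stsynth.SynthConfig(
        n_patients=2, cells_per_patient=40, n_genes=400, n_chromosomes=4,
        normal_cell_fraction=0.25, cnv_segments=((1, 10, 60, 0.5),),
        stem_set_size=20, invasive_set_size=20, g1s_set_size=10, g2m_set_size=10,
        alt_branch_set_size=15, housekeeping_count=20, cnv_window_hint=30,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return stsynth.generate_dataset(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
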