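import numpy as np
import pytest

from phenosim.casestudy import case_study_config
from phenosim.genotypes import GenotypeData
from phenosim.pipeline import run_simulation


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_panel() -> GenotypeData:
    """A fixed 5 x 3 hard-call panel with named samples and SNPs."""
    dosages = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [0, 2, 2],
            [1, 0, 0],
        ],
        dtype=float,
    )
    return GenotypeData(
        dosages=dosages,
        sample_ids=[f"s{i}" for i in range(1, 6)],
        snp_ids=["rs1", "rs2", "rs3"],
        chromosomes=["1", "1", "2"],
        positions=[100, 2000, 350],
        allele_freqs=dosages.mean(axis=0) / 2.0,
    )


@pytest.fixture(scope="session")
def case_result():
    """One reduced-scale case-study run shared across tests."""
    result, _ = run_simulation(case_study_config(seed=11))
    return result
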