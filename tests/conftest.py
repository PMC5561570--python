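import numpy as np
import pandas as pd
import pytest

from mqtlsmoke.config import PipelineConfig, SimulationConfig
from mqtlsmoke.deconvolution import estimate_proportions_matrix
from mqtlsmoke.models import PanelData
from mqtlsmoke.simulate import simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale two-panel study: 10 CpGs x 6 SNPs, 150/100 samples."""
    return SimulationConfig(
        n_discovery=150,
        n_validation=100,
        n_cpgs=10,
        snps_per_cpg=6,
        n_reference_cpgs=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_panels(small_study):
    """(discovery, validation, pooled) PanelData with estimated cell props."""
    props = estimate_proportions_matrix(
        small_study.reference_betas, small_study.reference
    )

    def make(which):
        cohort = small_study.cohort
        mask = slice(None) if which is None else cohort["panel"] == which
        sub = cohort[mask] if which is not None else cohort
        ids = pd.Index(sub["sample_id"])
        return PanelData(
            cohort=sub.set_index("sample_id"),
            betas=small_study.methylation.betas.loc[ids],
            dosages=small_study.genotypes.dosages.loc[ids],
            cell_props=props.loc[ids],
        )

    return make("discovery"), make("validation"), make(None)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
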