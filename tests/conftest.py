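import numpy as np
import pandas as pd
import pytest

from oxyhmc.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """500 CpGs x 30 samples at the default study conditions."""
    cfg = SimConfig(n_cpgs=500, n_samples=30, n_low=15, n_high=15, seed=1)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_annotation():
    """Hand-built 10-probe annotation covering all strata and both sexes."""
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:02d}" for i in range(10)],
            "chromosome": ["chr1"] * 4 + ["chr2"] * 3 + ["chrX", "chrX", "chrY"],
            "position": [100, 1000, 2000, 3000, 500, 1500, 2500, 100, 200, 300],
            "stratum": ["island", "shore", "shelf", "ocean"] * 2 + ["island", "ocean"],
            "gene_region": ["promoter", "exon", "intron", "intergenic"] * 2
            + ["promoter", "intron"],
            "tss_distance": [0, -500, 3000, -8000, 100, 2600, 12000, 50, -60, 70],
            "strand": ["+", "-"] * 5,
        }
    ).set_index("probe_id")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
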