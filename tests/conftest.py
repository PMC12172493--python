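import numpy as np
import pandas as pd
import pytest

from medimix import CountTable
from medimix.io import validate_metadata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixed_domain_table():
    """3 OTUs spanning Bacteria/Archaea/Eukarya over 4 samples."""
    counts = np.array(
        [
            [10, 20, 30, 40],
            [1, 2, 3, 4],
            [5, 6, 7, 8],
        ]
    )
    lineages = [
        "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus",
        "Archaea;Euryarchaeota;;;;",
        "Eukarya;Ascomycota;;;;",
    ]
    return CountTable(counts, ["otu1", "otu2", "otu3"], lineages,
                      ["s1", "s2", "s3", "s4"])


@pytest.fixture
def genus_table(rng):
    """Random 8-genus x 12-sample bacterial table with ample depth."""
    counts = rng.integers(0, 800, size=(8, 12))
    counts[0] += 500  # keep every sample comfortably above depth threshold
    genera = [f"Genus{i}" for i in range(8)]
    lineages = [f"Bacteria;P;C;O;F;{g}" for g in genera]
    return CountTable(counts, genera, lineages, [f"s{j}" for j in range(12)])


@pytest.fixture
def toy_metadata():
    df = pd.DataFrame(
        dict(
            sample_id=[f"s{j}" for j in range(12)],
            cluster_id=[f"p{j // 3}" for j in range(12)],
            clinical_state=["baseline", "exacerbation", "treatment"] * 4,
            # aggressiveness is a patient-level phenotype: constant in cluster
            aggressiveness=np.repeat(
                ["mild", "moderate_severe", "mild", "moderate_severe"], 3
            ),
            age=np.linspace(10, 50, 12),
            fev1_pct=np.linspace(40, 90, 12),
        )
    )
    return validate_metadata(df)
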