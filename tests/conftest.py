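import numpy as np
import pandas as pd
import pytest

import aggscan as ag


@pytest.fixture()
def toy_genotypes() -> ag.GenotypeMatrix:
    """Hand-constructed 8-strain, 5-marker chromosome for QC tests.

    m1 and m2 are duplicates (R^2 = 1); m5 is monomorphic (MAF 0).
    """
    alleles = np.array(
        [
            [0, 0, 1, 0, 0],
            [0, 0, 0, 1, 0],
            [1, 1, 0, 0, 0],
            [1, 1, 1, 1, 0],
            [0, 0, 0, 0, 0],
            [1, 1, 1, 0, 0],
            [0, 0, 1, 1, 0],
            [1, 1, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    meta = pd.DataFrame(
        {"chrom": ["c1"] * 5, "pos": range(1, 6), "name": [f"m{i}" for i in range(1, 6)]}
    )
    return ag.GenotypeMatrix(alleles, meta, [f"s{i}" for i in range(8)])


@pytest.fixture(scope="session")
def noiseless_field():
    """A 40-cell noiseless rendered field with 25% of fluorescent cells bearing foci."""
    truth = ag.sample_field_truth(
        40, 0.8, 0.25, (512, 512), seed=3, noise_sd=0.0
    )
    dic, gfp = ag.render_field(truth, (512, 512), seed=4)
    return truth, dic, gfp
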