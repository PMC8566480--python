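import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from eprsqol.genotypes import GenotypeMatrix
from eprsqol.simulate import simulate_study


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study (shared across tests)."""
    return simulate_study(
        n_samples=500, n_markers=480, n_genes=48, snps_per_gene=8, seed=11
    )


@pytest.fixture(scope="session")
def small_analysis(small_bundle):
    from eprsqol.pipeline import build_analysis_table

    data, _ = build_analysis_table(
        small_bundle.genotypes, small_bundle.weights, small_bundle.cohort
    )
    return data


@pytest.fixture()
def tiny_genotypes():
    """3 samples x 3 markers with one missing call."""
    dos = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, np.nan, 0.0],
            [2.0, 2.0, 1.0],
        ]
    )
    markers = pd.DataFrame(
        {
            "snp_id": ["m1", "m2", "m3"],
            "chrom": [1, 1, 2],
            "pos": [1000, 500_000, 1000],
            "ref": ["A", "G", "T"],
            "alt": ["G", "C", "C"],
        }
    )
    return GenotypeMatrix(dos, ["s1", "s2", "s3"], markers)


def make_weights(rows):
    """Helper: weight table from (snp_id, chrom, pos, ea, oa, gene, beta, sign, p)."""
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "gene", "beta", "sign", "clump_p",
        ],
    )
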