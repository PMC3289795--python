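import numpy as np
import pytest

from grsnbc.data import GenotypeMatrix, PhenotypeVector
from grsnbc.simulate import SimulationDesign


@pytest.fixture
def small_tsv(tmp_path):
    """3 subjects x 2 SNPs, one heterozygote written in reversed allele order."""
    content = (
        "subject_id\tphenotype\trs1:A/G\trs2:C/T\n"
        "s1\t1\tAA\tCT\n"
        "s2\t0\tGA\tTT\n"
        "s3\t1\t..\tCC\n"
    )
    path = tmp_path / "small.tsv"
    path.write_text(content)
    return path


@pytest.fixture
def tiny_matrix():
    codes = np.array([[0, 1], [1, 2], [-1, 0], [2, 2]], dtype=np.int8)
    matrix = GenotypeMatrix(
        subject_ids=("a", "b", "c", "d"),
        snp_ids=("rs1", "rs2"),
        alleles=(("A", "G"), ("C", "T")),
        codes=codes,
    )
    phenotype = PhenotypeVector(("a", "b", "c", "d"), np.array([1, 1, 0, 0], dtype=np.int8))
    return matrix, phenotype


@pytest.fixture(scope="session")
def mixed_design():
    """18 causal SNPs over all three modes plus 2 nulls; 500/500 subjects."""
    return SimulationDesign(
        n_cases=500,
        n_controls=500,
        or_grid=(1.5, 2.0),
        maf_grid=(0.1, 0.3, 0.5),
        modes=("additive", "recessive", "dominant"),
        n_null=2,
        n_replicates=2,
        seed=20240901,
    )


@pytest.fixture(scope="session")
def mixed_dataset(mixed_design):
    from grsnbc.simulate import simulate_dataset

    return simulate_dataset(mixed_design)
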