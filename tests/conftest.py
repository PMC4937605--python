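import numpy as np
import pytest

from orthovar.core_data import SampleDesign
from orthovar.synthetic_data import default_design, default_species_tree


@pytest.fixture(scope="session")
def design_2x2():
    index = {
        ("sp1", "orgA"): "sp1_A",
        ("sp1", "orgB"): "sp1_B",
        ("sp2", "orgA"): "sp2_A",
        ("sp2", "orgB"): "sp2_B",
    }
    return SampleDesign(("orgA", "orgB"), ("sp1", "sp2"), index)


@pytest.fixture(scope="session")
def design_6x7():
    return default_design()


@pytest.fixture(scope="session")
def species_tree():
    return default_species_tree()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_matrix_files(tmp_path):
    """2-species × 2-organ TSV pair with 3 genes."""
    matrix = tmp_path / "matrix.tsv"
    samples = tmp_path / "samples.tsv"
    matrix.write_text(
        "gene_id\tsp1_A\tsp1_B\tsp2_A\tsp2_B\n"
        "g1\t1.0\t2.0\t3.0\t4.0\n"
        "g2\t0.0\t0.5\t0.0\t0.5\n"
        "g3\t10.0\t20.0\t30.0\t40.0\n"
    )
    samples.write_text(
        "sample_id\tspecies\torgan\n"
        "sp1_A\tsp1\torgA\n"
        "sp1_B\tsp1\torgB\n"
        "sp2_A\tsp2\torgA\n"
        "sp2_B\tsp2\torgB\n"
    )
    return matrix, samples
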