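import numpy as np
import pytest

from regval.synthetic import make_toy_fold, simulate_distogram

TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 90.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 90.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00 90.00           C
ATOM      4  N   GLY A   2       2.000   0.000   1.300  1.00 90.00           N
ATOM      5  CA  GLY A   2       3.500   0.500   1.500  1.00 90.00           C
ATOM      6  N   ALA A   3       4.200   1.000   2.500  1.00 90.00           N
ATOM      7  CA  ALA A   3       5.500   1.500   3.000  1.00 90.00           C
ATOM      8  CB  ALA A   3       6.300   2.700   3.200  1.00 90.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture(scope="session")
def helix_chain():
    return make_toy_fold(60, "helix_bundle", seed=11)


@pytest.fixture(scope="session")
def helix_distogram(helix_chain):
    return simulate_distogram(helix_chain, sharpness=0.2, noise=0.0, seed=11)


@pytest.fixture(scope="session")
def default_classifier():
    from regval.classifier import load_default_classifier

    return load_default_classifier()


@pytest.fixture(scope="session")
def trained_benchmark():
    """Classifier trained on the default synthetic dataset (seed 1),
    shared across the tests that probe its behaviour."""
    from regval.evaluate import classifier_benchmark

    return classifier_benchmark(seed=1)
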