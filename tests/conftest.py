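import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ancres import Alignment, SubstitutionModel, read_newick

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lg_model():
    return SubstitutionModel.lg(alpha=0.7, n_categories=4)


@pytest.fixture(scope="session")
def lg_model_k2():
    """Two categories: keeps exhaustive-enumeration oracles fast."""
    return SubstitutionModel.lg(alpha=0.9, n_categories=2)


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:0.12,B:0.23)N2:0.07,C:0.31)N1;", is_path=False)


@pytest.fixture
def four_tip_tree():
    return read_newick(
        "((A:0.12,B:0.23)N2:0.07,(C:0.31,D:0.05)N3:0.18)N1;", is_path=False)


@pytest.fixture
def small_alignment():
    return Alignment.from_sequences(
        [("A", "MKV-A"), ("B", "M-VLA"), ("C", "LKXLA"), ("D", "AKVLG")])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20201225)
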