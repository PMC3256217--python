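import numpy as np
import pytest

from petromine.io import ProteinRef
from petromine.search import ScoringScheme
from petromine.simulate import FamilySpec, generate_reference_panel


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_families() -> tuple[FamilySpec, ...]:
    """Three compact families for fast unit tests."""
    return (
        FamilySpec(
            "alkane_1_monooxygenase", ("1.14.15.3",), ("O05895", "P12691"),
            ("Actinobacteria", "Gammaproteobacteria", "Alphaproteobacteria"),
            protein_length=120,
        ),
        FamilySpec(
            "catechol_2_3_dioxygenase", ("1.13.11.2", "1.13.11.39"),
            ("P06622", "Q53034"),
            ("Gammaproteobacteria", "Betaproteobacteria"),
            protein_length=120,
            synonym_families=(("biphenyl_2_3_diol_1_2_dioxygenase", "1.13.11.39"),),
        ),
        FamilySpec(
            "gentisate_1_2_dioxygenase", ("1.13.11.4",), ("Q13ZY3",),
            ("Betaproteobacteria", "Actinobacteria"),
            protein_length=120,
        ),
    )


@pytest.fixture(scope="session")
def small_panel(small_families) -> tuple[list[ProteinRef], list[ProteinRef]]:
    return generate_reference_panel(small_families, seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
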