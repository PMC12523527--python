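import pandas as pd
import pytest

from karstprior import GeneratorParams, generate_dataset

# Hand-built toy assemblage: 6 caves, 10 species (4 troglobionts t1-t4,
# 6 non-troglobionts n1-n6).  Ground truth enumerated by hand below.
_TOY_ROWS = [
    # cave  species  troglobiont
    ("A", "t1", True),   # t1 only in A  -> singleton
    ("A", "t2", True),   # t2 in A and B
    ("A", "n1", False),
    ("A", "n2", False),
    ("B", "t2", True),
    ("B", "t3", True),   # t3 in B, C, D
    ("B", "n1", False),
    ("B", "n3", False),
    ("B", "n4", False),
    ("C", "t3", True),
    ("C", "n5", False),
    ("D", "t3", True),
    ("D", "t4", True),   # t4 only in D  -> singleton
    ("D", "n1", False),
    ("D", "n2", False),
    ("D", "n3", False),
    ("D", "n6", False),
    ("E", "n1", False),  # E: no troglobionts
    ("F", "n6", False),  # F: single non-troglobite record
]

#: cave -> (nTS, TbS, EnD) enumerated by hand from _TOY_ROWS
TOY_TRUTH = {
    "A": (2, 2, 1),
    "B": (3, 2, 0),
    "C": (1, 1, 0),
    "D": (4, 2, 1),
    "E": (1, 0, 0),
    "F": (1, 0, 0),
}


@pytest.fixture
def toy_occurrences() -> pd.DataFrame:
    return pd.DataFrame(_TOY_ROWS, columns=["cave_id", "species_id", "troglobiont"])


@pytest.fixture(scope="session")
def default_dataset():
    """One default-parameter synthetic landscape, generated once."""
    return generate_dataset(GeneratorParams(seed=11))
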