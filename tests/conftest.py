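import numpy as np
import pytest

from nicheoverlap import CommunityMatrix, SpeciesMetadata


@pytest.fixture
def toy_matrix():
    """3 species x 3 sites with easy hand-checkable structure."""
    return CommunityMatrix(
        label="toy",
        species_ids=("sp1", "sp2", "sp3"),
        resource_ids=("A", "B", "C"),
        abundance=np.array([[2.0, 2.0, 0.0],
                            [0.0, 5.0, 0.0],
                            [1.0, 0.0, 3.0]]),
    )


@pytest.fixture
def toy_meta():
    return SpeciesMetadata({"sp1": "stygobite", "sp2": "stygobite",
                            "sp3": "non_stygobite", "sp4": "non_stygobite"})


@pytest.fixture
def identical_rows_matrix():
    """Every species uses the sites in identical proportions (overlap 1)."""
    return CommunityMatrix(
        label="ident",
        species_ids=("a", "b", "c"),
        resource_ids=("x", "y", "z"),
        abundance=np.array([[1.0, 2.0, 3.0],
                            [2.0, 4.0, 6.0],
                            [10.0, 20.0, 30.0]]),
    )
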