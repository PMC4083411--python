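import numpy as np
import pytest

from easemm.scales import default_table
from easemm.synthetic import SyntheticSpec, generate, heterogeneous_effects


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def small_bundle():
    """A small heterogeneous dataset with injected duplicates (~120 records)."""
    spec = SyntheticSpec(
        n_proteins=10,
        mutations_per_protein=12,
        effects=heterogeneous_effects(1.5),
        n_same_condition_duplicates=3,
        n_cross_condition_duplicates=2,
        seed=7,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_design(small_bundle):
    """Curated + encoded view of the small bundle."""
    records, X, descriptors, y, asa, ss, clusters = small_bundle.design_matrix()
    return {
        "records": records, "X": X, "descriptors": descriptors, "y": y,
        "asa": asa, "ss": ss, "clusters": clusters,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
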