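import io

import numpy as np
import pandas as pd
import pytest
import skbio

from migbiome.syndata import CohortDesign, PlantedBlock, generate_cohort


def make_ids(n):
    return [f"ASV{i + 1:04d}" for i in range(n)]


@pytest.fixture(scope="session")
def small_cohort():
    """Two-ethnicity, two-generation cohort with two planted blocks."""
    ids = make_ids(120)
    blocks = [
        PlantedBlock("BBB", ids[:10], {"A": -2.5, "B": -3.0},
                     {"A": 0.5, "B": 0.0}, 0.7),
        PlantedBlock("CMO", ids[10:18], {"A": -3.0, "B": -3.0},
                     {"A": -0.5, "B": 0.0}, 0.7),
    ]
    design = CohortDesign(
        ethnicities=["A", "B"],
        n_per_generation={"A": (20, 20), "B": (20, 20)},
        n_asvs=120,
        blocks=blocks,
        library_size_range=(2000, 3000),
        seed=11,
    )
    return design, generate_cohort(design)


@pytest.fixture(scope="session")
def six_tip_tree():
    """Fixed 6-tip tree with two clades hanging off the root."""
    nwk = "((A:0.1,B:0.2):0.3,((C:0.1,D:0.1):0.2,(E:0.3,F:0.1):0.1):0.2);"
    return skbio.TreeNode.read(io.StringIO(nwk))


@pytest.fixture(scope="session")
def six_tip_table():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 60, size=(4, 6))
    counts[0, 0] = 5  # ensure nonzero rows
    return pd.DataFrame(counts, index=[f"s{i}" for i in range(4)],
                        columns=list("ABCDEF"))
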