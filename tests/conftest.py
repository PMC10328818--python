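import numpy as np
import pandas as pd
import pytest

from permapart import CountTable, DistanceMatrix, SampleMetadata, VariableDef
from permapart.simulate import GeneratorConfig, demo_truth, simulate_cohort


def make_metadata(n, seed=0, **columns):
    """Minimal single-timepoint infant metadata with ad-hoc columns."""
    ids = [f"s{i}" for i in range(n)]
    base = {
        "subject_id": ids,
        "family_id": ids,
        "role": ["infant"] * n,
        "timepoint": ["3m"] * n,
    }
    base.update(columns)
    return SampleMetadata(pd.DataFrame(base, index=ids))


def euclid_dm(Y, ids=None):
    from scipy.spatial.distance import pdist, squareform

    ids = ids or [f"s{i}" for i in range(len(Y))]
    return DistanceMatrix(squareform(pdist(Y)), ids, "euclidean")


@pytest.fixture(scope="session")
def small_cohort():
    """Demo cohort with planted batch/delivery/sibling/stool effects."""
    cfg = GeneratorConfig(n_families=60, seed=42, timepoints=("3w", "3m", "12m"))
    return simulate_cohort(cfg, demo_truth())


@pytest.fixture(scope="session")
def tiny_counts():
    counts = pd.DataFrame(
        {
            "a": [5, 3, 2, 0],
            "b": [1, 1, 2, 6],
            "c": [10, 0, 0, 0],
        },
        index=[
            "Bacteroidaceae;Bacteroides",
            "Bifidobacteriaceae;Bifidobacterium",
            "Bacteroidaceae;Prevotella",
            "Lachnospiraceae;Blautia",
        ],
    )
    ranks = pd.Series("genus", index=counts.index)
    return CountTable(counts, ranks)
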