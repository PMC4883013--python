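import numpy as np
import pandas as pd
import pytest

from subfieldstats.datatypes import Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pedigree():
    """2 MZ pairs + 1 DZ pair."""
    rows = [
        ("a1", "famA", "MZ", "F", 25.0),
        ("a2", "famA", "MZ", "F", 25.0),
        ("b1", "famB", "MZ", "M", 30.0),
        ("b2", "famB", "MZ", "M", 30.0),
        ("c1", "famC", "DZ", "F", 22.0),
        ("c2", "famC", "DZ", "M", 22.0),
    ]
    return Pedigree(pd.DataFrame(
        rows, columns=["individual_id", "family_id", "zygosity", "sex", "age"]
    ))


def make_pedigree_frame(n_mz, n_dz, age=25.0):
    rows = []
    fam = 0
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        for _ in range(n):
            fam += 1
            for k in (1, 2):
                rows.append((f"f{fam:03d}_{k}", f"f{fam:03d}", zyg, "F", age))
    return pd.DataFrame(
        rows, columns=["individual_id", "family_id", "zygosity", "sex", "age"]
    )
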