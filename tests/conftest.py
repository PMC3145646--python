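import pandas as pd
import pytest

from gutsort.synthetic import (
    default_design,
    default_scenario,
    gen_community,
    gen_taxonomy,
    library_id,
    sample_counts,
)


def design_frame(design):
    return pd.DataFrame(
        [(library_id(s, f), s, f) for s, f in design],
        columns=["library_id", "sample", "fraction"],
    )


@pytest.fixture(scope="session")
def tree_small():
    return gen_taxonomy(3, 8, seed=11)


@pytest.fixture(scope="session")
def truth_default():
    return default_scenario(seed=1)


@pytest.fixture(scope="session")
def truth_small():
    tree = gen_taxonomy(3, 12, seed=11)
    return gen_community(default_design(2), knee_pct=1.0, n_orb=4, n_urb=8,
                         effects=None, seed=11, tree=tree)


@pytest.fixture(scope="session")
def percent_default(truth_default):
    from gutsort.metrics import normalize_percent

    return normalize_percent(sample_counts(truth_default, 2000, seed=1))


@pytest.fixture(scope="session")
def design_default(truth_default):
    return design_frame(truth_default.design)
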