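import pytest

import tagdge as t
from tagdge import simdata


@pytest.fixture(scope="session")
def small_design():
    return t.SyntheticDesign(n_genes=60, library_depth=8000,
                             gene_length_range=(100, 800), seed=3)


@pytest.fixture(scope="session")
def small_reference(small_design):
    return t.make_reference(small_design)


@pytest.fixture(scope="session")
def small_library(small_design, small_reference):
    _, truth = small_reference
    return t.simulate_library(truth, 0, small_design)


@pytest.fixture(scope="session")
def small_clean(small_library):
    return t.filter_raw_tags(small_library.reads,
                             adaptors=(simdata.ADAPTOR_1,),
                             library=small_library.library)


@pytest.fixture(scope="session")
def small_index(small_reference):
    records, _ = small_reference
    return t.build_index(records)
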