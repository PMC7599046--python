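import numpy as np
import pytest

import nichefit as nf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def recovery_model():
    return nf.default_recovery_model()


@pytest.fixture(scope="session")
def recovery_sample(recovery_model):
    """One community from the two-niche recovery fixture, with truth."""
    table, truth = nf.make_community(recovery_model, 500, seed=42, sample_id="rec0")
    return nf.abundance_vector(table, "rec0"), truth


@pytest.fixture(scope="session")
def small_otu_table(tmp_path_factory):
    path = tmp_path_factory.mktemp("otu") / "counts.tsv"
    path.write_text(
        "sample_id\tOTU1\tOTU2\tOTU3\n"
        "A\t0\t3\t11\n"
        "B\t5\t1\t0\n"
    )
    return path
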