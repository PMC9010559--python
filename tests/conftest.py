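import pandas as pd
import pytest

from splitreg.kinetics import PoolKinetics
from splitreg.nanostring import CountMatrix
from splitreg.simulate import default_isoform_kinetics, scenario_suite


@pytest.fixture(scope="session")
def default_kins():
    return default_isoform_kinetics()


@pytest.fixture(scope="session")
def default_pool():
    return PoolKinetics()


@pytest.fixture(scope="session")
def null_bundle():
    """Small null-scenario study reused across read-only tests."""
    return scenario_suite("null", seed=11)


@pytest.fixture(scope="session")
def colch_bundle():
    return scenario_suite("colchicine-6h", seed=3)


@pytest.fixture()
def tiny_count_matrix():
    """Hand-built 2-lane matrix where every factor is computable by hand."""
    probes = pd.DataFrame(
        {
            "gene": ["g1", "g1", "POS_A", "POS_B", "NEG_1", "NEG_2", "Gapdh"],
            "region": ["exon", "intron", None, None, None, None, None],
            "class": ["endogenous", "endogenous", "positive", "positive",
                      "negative", "negative", "housekeeping"],
            "expected_conc": [None, None, 128.0, 32.0, None, None, None],
        },
        index=pd.Index(["g1_exon", "g1_intron", "POS_A", "POS_B", "NEG_1", "NEG_2", "Gapdh"],
                       name="probe_id"),
    )
    counts = pd.DataFrame(
        {"s1": [500, 100, 100, 200, 4, 5, 1000], "s2": [1000, 200, 200, 400, 5, 4, 2000]},
        index=probes.index,
    )
    samples = pd.DataFrame({"group": ["Ctrl", "Treated"]}, index=pd.Index(["s1", "s2"], name="sample_id"))
    return CountMatrix(counts, probes, samples)
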