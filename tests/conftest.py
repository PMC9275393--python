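import numpy as np
import pytest

from clsig.annotate import Rearrangement
from clsig.reference import (
    AnalysisParameters,
    CellFraction,
    default_clan_table,
)
from clsig.simulate import toy_germline
from clsig.stereotypy import (
    ResidueClassTable,
    load_subset_definitions,
    synthetic_subsets_path,
)


@pytest.fixture(scope="session")
def clans():
    return default_clan_table()


@pytest.fixture(scope="session")
def germline():
    return toy_germline()


@pytest.fixture(scope="session")
def subset_defs(clans):
    return load_subset_definitions(synthetic_subsets_path(), clans)


@pytest.fixture(scope="session")
def classes():
    return ResidueClassTable()


@pytest.fixture(scope="session")
def params():
    return AnalysisParameters()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fraction():
    return CellFraction("D01", "POS", "KAPPA", "N")


def make_rearrangement(
    seq_id="R0",
    cdr3="ARDFGW",
    v_call="IGHV1-2",
    j_call="IGHJ4",
    mut=0.5,
    read_count=1,
    fraction=None,
    donor="D01",
):
    """Minimal synthetic annotated rearrangement for clonotype/assignment tests."""
    fraction = fraction or CellFraction(donor, "POS", "KAPPA", "N")
    junction = "C" + cdr3 + "W"
    return Rearrangement(
        sequence_id=seq_id,
        sequence="ACGT" * 30,
        v_call=v_call,
        j_call=j_call,
        junction_aa=junction,
        v_mutation_pct=mut,
        productive=True,
        fraction=fraction,
        read_count=read_count,
    )
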