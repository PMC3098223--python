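import numpy as np
import pytest

from lignoflux.data import INTERNODES, generate_synthetic_study, anchor_fixtures
from lignoflux.fba import (
    FBAProblem,
    MonomerComposition,
    enumerate_alternate_optima,
    select_reference_distribution,
    solve_fba,
    wildtype_reference,
)
from lignoflux.network import build_reference_network


@pytest.fixture(scope="session")
def ext_net():
    return build_reference_network("extended")


@pytest.fixture(scope="session")
def unext_net():
    return build_reference_network("unextended")


@pytest.fixture(scope="session")
def printed_comp():
    """The printed internode 1-2 wild-type composition."""
    return MonomerComposition.from_percent(7.0, 85.5, 7.4)


@pytest.fixture(scope="session")
def wt12_problem(ext_net, printed_comp):
    return FBAProblem(ext_net, printed_comp)


@pytest.fixture(scope="session")
def wt12_optimum(wt12_problem):
    return solve_fba(wt12_problem)


@pytest.fixture(scope="session")
def wt12_vertices(wt12_problem, wt12_optimum):
    return enumerate_alternate_optima(wt12_problem, wt12_optimum)


@pytest.fixture(scope="session")
def wt12_mainroute(wt12_vertices):
    return select_reference_distribution(wt12_vertices, "main-route")


@pytest.fixture(scope="session")
def synth_table():
    return generate_synthetic_study(seed=7)


@pytest.fixture(scope="session")
def fixture_table():
    return anchor_fixtures()


def comp_of(table, line, internode) -> MonomerComposition:
    row = table[(table.line_id == line) & (table.internode == internode)].iloc[0]
    return MonomerComposition.from_percent(row.h_pct, row.g_pct, row.s_pct)


@pytest.fixture(scope="session")
def wt_refs(ext_net, synth_table):
    """Main-route wild-type references for all seven internodes."""
    return {
        key: wildtype_reference(FBAProblem(ext_net, comp_of(synth_table, "WT", key)),
                                "main-route")
        for key in INTERNODES
    }
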