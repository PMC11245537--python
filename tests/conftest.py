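import pytest

from abseqmap.core import CellRecord, Clonotype, Repertoire, SingleCellRepertoire
from abseqmap.simulate import SimulationConfig, default_germline


@pytest.fixture(scope="session")
def heavy_germline():
    return default_germline("heavy")


@pytest.fixture(scope="session")
def light_germline():
    return default_germline("kappa")


def make_clonotype(
    cdr3="CARDW",
    v="IGHV1-2",
    j="IGHJ4",
    chain="heavy",
    isotype="IgM",
    size=1,
    prefix="EVQLV",
    suffix="GQGTL",
    cdr3_nt=None,
    productive=True,
):
    vdj = prefix + cdr3 + suffix
    return Clonotype(
        chain=chain,
        v_gene=v,
        j_gene=j,
        isotype=isotype if chain == "heavy" else "none",
        cdr3_aa=cdr3,
        vdj_aa=vdj,
        cdr3_span=(len(prefix), len(prefix) + len(cdr3)),
        size=size,
        cdr3_nt=cdr3_nt,
        productive=productive,
    )


def make_repertoire(clonotypes, sample_id="S1", donor="D1", method="bulk", **kw):
    return Repertoire(
        sample_id=sample_id, donor=donor, method=method, clonotypes=list(clonotypes), **kw
    )


def make_cell(cell_id, heavy, light):
    return CellRecord(cell_id=cell_id, heavy=heavy, light=light)


def make_sc_repertoire(cells, sample_id="SC1", donor="D1"):
    return SingleCellRepertoire.from_cells(cells, sample_id=sample_id, donor=donor)


@pytest.fixture
def tiny_bulk():
    cts = [
        make_clonotype(cdr3="CARAW", v="IGHV1-2", size=10),
        make_clonotype(cdr3="CARCW", v="IGHV1-2", size=5),
        make_clonotype(cdr3="CARDW", v="IGHV3-7", size=5),
        make_clonotype(cdr3="CAREW", v="IGHV4-4", size=1),
    ]
    return make_repertoire(cts)


@pytest.fixture
def base_config():
    return SimulationConfig(n_clonotypes=500, seed=42)
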