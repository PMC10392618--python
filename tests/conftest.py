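import pytest

from qtykit import (
    FixtureSpec,
    ProteinRecord,
    TMSegment,
    TMTopology,
    apply_qty,
    ideal_helix_coords,
    synthetic_transporter,
)


@pytest.fixture
def livf_variant():
    """The canonical four-residue example: LIVF fully inside one helix."""
    record = ProteinRecord("toy", sequence="LIVF")
    topo = TMTopology((TMSegment(1, 4, "TM1"),))
    return apply_qty(record, topo)


@pytest.fixture
def transporter():
    """One synthetic 12-TM transporter (seed 1) and its topology."""
    return synthetic_transporter(FixtureSpec(seed=1))


@pytest.fixture
def transporter_variant(transporter):
    record, topo = transporter
    return apply_qty(record, topo)


@pytest.fixture
def helix_model(transporter):
    record, _ = transporter
    return ideal_helix_coords(record.sequence)
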