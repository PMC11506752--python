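import pytest
from hypothesis import settings

import mitoprofile as mp

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table1():
    """The packaged S. dorsalis annotation table (table-only genome)."""
    return mp.load_table1()


@pytest.fixture(scope="session")
def sim_genome():
    """One deterministic synthetic mitogenome under the study conditions."""
    return mp.generate_mitogenome(mp.SimulationSpec(seed=101))


@pytest.fixture(scope="session")
def code():
    return mp.VERTEBRATE_MITO


@pytest.fixture()
def toy_genome():
    """8-nt circular toy genome with one gene per strand case."""
    return mp.AnnotatedMitogenome(
        sequence=mp.NucSequence("ATGCATGC", circular=True),
        genes=[
            mp.GeneRecord("fwd", mp.GeneKind.PCG, 1, 3, mp.Strand.H),
            mp.GeneRecord("rev", mp.GeneKind.TRNA, 4, 6, mp.Strand.L),
            mp.GeneRecord("wrap", mp.GeneKind.TRNA, 7, 2, mp.Strand.H),
        ])
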