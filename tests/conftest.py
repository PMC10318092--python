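import pytest

from htearray import (
    FactorSet,
    PlateFormat,
    ReagentClass,
    auto_layout,
    synth_inventory,
)

FIG_COUNTS = {
    ReagentClass.LIGAND1: 4,
    ReagentClass.CATALYST1: 3,
    ReagentClass.ADDITIVE: 2,
    ReagentClass.ELECTROPHILE: 1,
    ReagentClass.NUCLEOPHILE: 1,
    ReagentClass.SOLVENT1: 1,
}


@pytest.fixture(scope="session")
def multiplex_inventory():
    """4 ligands x 3 catalysts x 2 additives plus substrates and solvent."""
    return synth_inventory(FIG_COUNTS, seed=11)


@pytest.fixture(scope="session")
def multiplex_factors(multiplex_inventory):
    return FactorSet(
        groups={c: multiplex_inventory.by_class(c) for c in FIG_COUNTS}
    )


@pytest.fixture()
def design24(multiplex_factors):
    """The 4x6 multiplexed 24-well design (rebuilt per test: it is mutable)."""
    return auto_layout(multiplex_factors, PlateFormat(24), name="demo24")


@pytest.fixture(scope="session")
def ultra_factors():
    """80 amines x 8 conditions, run in duplicate, on a 1536-well plate."""
    inv = synth_inventory(
        {
            ReagentClass.NUCLEOPHILE: 80,
            ReagentClass.OTHER: 8,
            ReagentClass.ELECTROPHILE: 1,
            ReagentClass.SOLVENT1: 1,
        },
        seed=13,
    )
    return FactorSet(
        groups={
            c: inv.by_class(c)
            for c in (
                ReagentClass.NUCLEOPHILE,
                ReagentClass.OTHER,
                ReagentClass.ELECTROPHILE,
                ReagentClass.SOLVENT1,
            )
        },
        replicates=2,
    )
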