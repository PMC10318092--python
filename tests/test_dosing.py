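import random

import pytest

from htearray import (
    DoseSpec,
    DosingError,
    FactorSet,
    PlateDesign,
    PlateFormat,
    ReactionSpec,
    Reagent,
    ReagentClass,
    WellAddress,
    auto_layout,
    build_plan,
    human_instructions,
    per_well_amounts,
    robot_worklist,
    write_worklist,
)
from htearray.dosing import DosingPlan


def _reagent(name, cls=ReagentClass.OTHER, mw=190.0):
    return Reagent(name=name, molecular_weight=mw, reagent_class=cls)


SOLVENT = _reagent("MeCN", ReagentClass.SOLVENT1, 41.05)


def _spec(well, doses, scale=0.01, volume=100.0):
    return ReactionSpec(
        well=well, doses=doses, solvent=SOLVENT, scale=scale, total_volume=volume
    )


class TestPerWellAmounts:
    def test_catalyst_at_20_mol_percent(self):
        cat = _reagent("CuBr", ReagentClass.CATALYST1)
        sub = _reagent("substrate", ReagentClass.ELECTROPHILE)
        spec = _spec(
            WellAddress(0, 0),
            [
                DoseSpec(reagent=sub, loading=1.0, stock_concentration=0.5),
                DoseSpec(reagent=cat, loading=0.20, stock_concentration=0.1),
            ],
        )
        amounts = per_well_amounts(spec)
        assert amounts[cat] == pytest.approx(0.002)
        assert amounts[sub] == pytest.approx(0.01)

    def test_excess_base_at_three_equivalents(self):
        base = _reagent("Cs2CO3", ReagentClass.BASE_ACID, 325.82)
        sub = _reagent("substrate", ReagentClass.ELECTROPHILE)
        spec = _spec(
            WellAddress(0, 0),
            [
                DoseSpec(reagent=sub, loading=1.0, stock_concentration=0.5),
                DoseSpec(reagent=base, loading=3.0, stock_concentration=0.5),
            ],
        )
        assert per_well_amounts(spec)[base] == pytest.approx(0.03)

    def test_no_limiting_reagent_is_an_error(self):
        cat = _reagent("cat", ReagentClass.CATALYST1)
        spec = _spec(
            WellAddress(0, 0),
            [DoseSpec(reagent=cat, loading=0.2, stock_concentration=0.1)],
        )
        with pytest.raises(ValueError, match="limiting"):
            per_well_amounts(spec)


class TestBuildPlan:
    def test_hand_derived_stock_recipe(self):
        """24 wells x 0.002 mmol from a 0.1 M stock.

        Hand arithmetic: 20 uL per well, 480 uL dispensed, 576 uL prepared
        at 20% dead volume, and 0.1 M x 576 uL x 190 g/mol x 1e-3 = 10.944 mg.
        """
        cat = _reagent("catalyst", ReagentClass.CATALYST1, mw=190.0)
        sub = _reagent("substrate", ReagentClass.ELECTROPHILE)
        design = PlateDesign(name="p", format=PlateFormat(24))
        for well in [WellAddress(r, c) for r in range(4) for c in range(6)]:
            design.reactions[well] = _spec(
                well,
                [
                    DoseSpec(reagent=sub, loading=1.0, stock_concentration=0.5),
                    DoseSpec(reagent=cat, loading=0.20, stock_concentration=0.1),
                ],
            )
        plan = build_plan(design, dead_volume_fraction=0.20)
        stock = next(s for s in plan.stocks if s.reagent.name == "catalyst")
        aliquots = [t for t in plan.transfers if t.source == stock.id]
        assert all(t.volume == pytest.approx(20.0) for t in aliquots)
        assert sum(t.volume for t in aliquots) == pytest.approx(480.0)
        assert stock.prepared_volume == pytest.approx(576.0)
        assert stock.reagent_mass == pytest.approx(10.944)

    def test_single_well_single_reagent(self):
        sub = _reagent("s", ReagentClass.ELECTROPHILE)
        design = PlateDesign(name="p", format=PlateFormat(24))
        w = WellAddress(0, 0)
        design.reactions[w] = _spec(
            w, [DoseSpec(reagent=sub, loading=1.0, stock_concentration=0.5)]
        )
        plan = build_plan(design, dead_volume_fraction=0.0)
        reagent_stocks = [s for s in plan.stocks if not s.neat]
        assert len(reagent_stocks) == 1
        aliquots = [t for t in plan.transfers if t.source == reagent_stocks[0].id]
        assert len(aliquots) == 1
        assert aliquots[0].volume == pytest.approx(20.0)

    def test_zero_dead_volume_exact(self):
        sub = _reagent("s", ReagentClass.ELECTROPHILE)
        design = PlateDesign(name="p", format=PlateFormat(24))
        for c in range(6):
            w = WellAddress(0, c)
            design.reactions[w] = _spec(
                w, [DoseSpec(reagent=sub, loading=1.0, stock_concentration=0.5)]
            )
        plan = build_plan(design, dead_volume_fraction=0.0)
        for stock in plan.stocks:
            out = sum(t.volume for t in plan.transfers if t.source == stock.id)
            assert stock.prepared_volume == pytest.approx(out)

    def test_sub_minimum_aliquot_rejected(self):
        sub = _reagent("s", ReagentClass.ELECTROPHILE)
        design = PlateDesign(name="p", format=PlateFormat(24))
        w = WellAddress(0, 0)
        design.reactions[w] = _spec(
            w,
            [DoseSpec(reagent=sub, loading=1.0, stock_concentration=0.5)],
            scale=0.0001,  # 0.2 uL aliquot
        )
        with pytest.raises(DosingError, match="minimum"):
            build_plan(design)

    def test_overfilled_well_rejected(self):
        sub = _reagent("s", ReagentClass.ELECTROPHILE)
        design = PlateDesign(name="p", format=PlateFormat(24))
        w = WellAddress(0, 0)
        design.reactions[w] = _spec(
            w,
            [DoseSpec(reagent=sub, loading=1.0, stock_concentration=0.5)],
            scale=0.1,  # 200 uL into a 100 uL well
        )
        with pytest.raises(DosingError, match="exceeds"):
            build_plan(design)


def _random_design(rng):
    classes = [
        ReagentClass.ELECTROPHILE,
        ReagentClass.NUCLEOPHILE,
        ReagentClass.CATALYST1,
        ReagentClass.LIGAND1,
    ]
    groups = {
        ReagentClass.SOLVENT1: [SOLVENT],
        ReagentClass.ELECTROPHILE: [
            _reagent("e0", ReagentClass.ELECTROPHILE, rng.uniform(80, 400))
        ],
    }
    for cls in rng.sample(classes[1:], rng.randint(1, 3)):
        groups[cls] = [
            _reagent(f"{cls.slug}-{i}", cls, rng.uniform(80, 400))
            for i in range(rng.randint(1, 4))
        ]
    fs = FactorSet(
        groups=groups,
        scale=rng.choice([0.005, 0.01]),
        total_volume=rng.choice([100.0, 150.0]),
    )
    return auto_layout(fs, PlateFormat(96))


@pytest.mark.parametrize("seed", range(10))
def test_volume_conservation_and_mole_balance(seed):
    """Prepared volume covers outgoing transfers; transfers re-derive mmol.

    For every stock: prepared >= sum(transfers), equal at zero dead volume;
    per well, transfer volume x stock molarity recovers the dosed mmol
    within 1e-6, and doses + solvent top-up hit the reaction volume.
    """
    rng = random.Random(seed)
    design = _random_design(rng)
    dead = rng.choice([0.0, 0.1, 0.2])
    plan = build_plan(design, dead_volume_fraction=dead)

    by_stock = {}
    for t in plan.transfers:
        by_stock.setdefault(t.source, []).append(t)
    for stock in plan.stocks:
        out = sum(t.volume for t in by_stock.get(stock.id, []))
        assert stock.prepared_volume >= out - 1e-9
        if dead == 0.0:
            assert stock.prepared_volume == pytest.approx(out)
        if not stock.neat:
            # mass-concentration consistency, 0.1%
            expected = stock.concentration * stock.prepared_volume * stock.reagent.molecular_weight * 1e-3
            assert stock.reagent_mass == pytest.approx(expected, rel=1e-3)

    stocks = {s.id: s for s in plan.stocks}
    per_well_vol = {}
    per_well_mmol = {}
    for t in plan.transfers:
        per_well_vol[t.destination] = per_well_vol.get(t.destination, 0.0) + t.volume
        s = stocks[t.source]
        if not s.neat:
            key = (t.destination, s.reagent.name)
            per_well_mmol[key] = per_well_mmol.get(key, 0.0) + t.volume * s.concentration / 1000.0
    for well, spec in design.reactions.items():
        assert per_well_vol[well] == pytest.approx(spec.total_volume, abs=0.01)
        for reagent, mmol in per_well_amounts(spec).items():
            assert per_well_mmol[(well, reagent.name)] == pytest.approx(mmol, abs=1e-6)


class TestRendering:
    def _one_stock_plan(self):
        sub = _reagent("s", ReagentClass.ELECTROPHILE)
        design = PlateDesign(name="p", format=PlateFormat(24))
        for c in range(3):
            w = WellAddress(0, c)
            design.reactions[w] = _spec(
                w, [DoseSpec(reagent=sub, loading=1.0, stock_concentration=0.5)]
            )
        return build_plan(design)

    def test_instructions_prepare_then_distribute(self):
        plan = self._one_stock_plan()
        lines = human_instructions(plan).splitlines()
        # one reagent stock + one solvent top-up source, each prepared then distributed
        assert len(lines) == 4
        assert lines[0].startswith("1. Weigh")
        assert "Distribute" in lines[2]
        assert "A1, A2, A3" in lines[2]

    def test_empty_plan_renders_empty(self):
        assert human_instructions(DosingPlan()) == ""

    def test_worklist_rows_and_formatting(self):
        plan = self._one_stock_plan()
        rows = robot_worklist(plan)
        assert len(rows) == len(plan.transfers) == 6
        assert rows[0] == ("S001", "A1", "20.0")  # fixed one-decimal format
        for stock in plan.stocks:
            total = sum(float(v) for s, _, v in rows if s == stock.source_location)
            assert total <= stock.prepared_volume + 1e-9

    def test_worklist_csv(self, tmp_path):
        plan = self._one_stock_plan()
        path = tmp_path / "wl.csv"
        write_worklist(plan, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "source,destination,volume_ul"
        assert lines[1] == "S001,A1,20.0"
        assert len(lines) == 7
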