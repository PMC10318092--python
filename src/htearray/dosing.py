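"""Stoichiometry engine: stock-solution recipes and transfer lists.

Unit conventions: amounts in mmol, volumes in uL, concentrations in mol/L,
masses in mg, molecular weights in g/mol. The aliquot volume of a dose is
v = 1000 x mmol / M; the solid charged to a stock vial is
mass = M x prepared_volume x MW x 1e-3 (mg). Each well is brought to its
reaction volume with a neat solvent top-up.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

from .core_model import (
    HteArrayError,
    PlateDesign,
    ReactionSpec,
    Reagent,
    WellAddress,
)

#: Excess fraction of stock prepared beyond the dispensed total, to cover
#: pipetting losses.
DEFAULT_DEAD_VOLUME_FRACTION = 0.20

#: Smallest transfer a mosquito-class liquid handler dispenses reliably (uL).
MIN_PIPETTABLE_UL = 0.5

_VOL_TOL_UL = 0.01


class DosingError(HteArrayError):
    """A dosing plan cannot be built or rendered."""


@dataclass
class StockSolution:
    """A source vial: one reagent dissolved (or suspended) at a set molarity.

    ``neat`` stocks are undiluted liquids (the solvent top-up source);
    they carry a dispensed volume but no concentration/mass bookkeeping.
    """

    id: str
    reagent: Reagent
    solvent: Reagent
    concentration: float  # mol/L; 0 for neat liquids
    prepared_volume: float  # uL
    reagent_mass: Optional[float] = None  # mg, solids dosed as solutions
    reagent_volume: Optional[float] = None  # uL, neat liquids via density
    source_location: Optional[str] = None
    suspension: bool = False
    neat: bool = False


@dataclass(frozen=True)
class Transfer:
    """One aliquot from a stock to a destination well."""

    source: str  # StockSolution id
    destination: WellAddress
    volume: float  # uL


@dataclass
class DosingPlan:
    """Stocks plus the full transfer list realizing a plate design."""

    stocks: list[StockSolution] = field(default_factory=list)
    transfers: list[Transfer] = field(default_factory=list)
    dead_volume_fraction: float = DEFAULT_DEAD_VOLUME_FRACTION

    def stock(self, stock_id: str) -> StockSolution:
        for s in self.stocks:
            if s.id == stock_id:
                return s
        raise KeyError(stock_id)


def per_well_amounts(spec: ReactionSpec) -> dict[Reagent, float]:
    """mmol of every dosed reagent: amount = scale x loading.

    The scale is defined by the limiting reagent (loading 1.0 or explicitly
    tagged); raises if none is identifiable.
    """
    spec.limiting_dose()  # raises if no limiting reagent
    amounts: dict[Reagent, float] = {}
    for dose in spec.doses:
        amounts[dose.reagent] = amounts.get(dose.reagent, 0.0) + spec.scale * dose.loading
    return amounts


def aliquot_volume_ul(amount_mmol: float, concentration_m: float) -> float:
    """uL of stock delivering the given mmol: v = 1000 x mmol / M."""
    return 1000.0 * amount_mmol / concentration_m


def build_plan(
    design: PlateDesign,
    dead_volume_fraction: float = DEFAULT_DEAD_VOLUME_FRACTION,
    min_volume: float = MIN_PIPETTABLE_UL,
    suspensions: frozenset[str] = frozenset(),
) -> DosingPlan:
    """Turn a plate design into stock recipes plus a transfer list.

    One stock is made per (reagent, concentration, solvent) triple;
    its prepared volume is the dispensed total times (1 + dead volume
    fraction), and the mass to weigh follows from the molarity. A neat
    solvent stock per solvent supplies the top-up that brings each well to
    its reaction volume. Reagent names in ``suspensions`` are flagged as
    suspensions in the instructions but computed identically.

    Raises :class:`DosingError` when a reagent aliquot falls below the
    minimum pipettable volume or the summed doses exceed the well volume.
    """
    if dead_volume_fraction < 0:
        raise DosingError("dead_volume_fraction must be >= 0")

    # (reagent name, concentration, solvent name) -> [stock, aliquot transfers]
    groups: dict[tuple[str, float, str], list] = {}
    solvent_needs: dict[str, list[tuple[Reagent, WellAddress, float]]] = {}

    for well in design.occupied_wells():
        spec = design.reactions[well]
        spec.limiting_dose()  # every reaction must define its scale
        dosed = 0.0
        for dose in spec.doses:
            amount = spec.scale * dose.loading
            vol = aliquot_volume_ul(amount, dose.stock_concentration)
            if vol < min_volume:
                raise DosingError(
                    f"well {well.label}: {dose.reagent.name} aliquot "
                    f"{vol:.3g} uL is below the {min_volume} uL minimum; "
                    "lower the stock concentration"
                )
            dosed += vol
            key = (dose.reagent.name, dose.stock_concentration, spec.solvent.name)
            groups.setdefault(key, [dose.reagent, spec.solvent, []])[2].append(
                (well, vol)
            )
        if dosed > spec.total_volume + _VOL_TOL_UL:
            raise DosingError(
                f"well {well.label}: dosed volume {dosed:.2f} uL exceeds the "
                f"{spec.total_volume:.2f} uL well volume"
            )
        topup = spec.total_volume - dosed
        if topup > _VOL_TOL_UL:
            solvent_needs.setdefault(spec.solvent.name, []).append(
                (spec.solvent, well, topup)
            )

    plan = DosingPlan(dead_volume_fraction=dead_volume_fraction)
    n = 0
    for (rname, conc, sname), (reagent, solvent, aliquots) in sorted(
        groups.items()
    ):
        n += 1
        dispensed = sum(v for _, v in aliquots)
        prepared = dispensed * (1.0 + dead_volume_fraction)
        stock = StockSolution(
            id=f"S{n:03d}",
            reagent=reagent,
            solvent=solvent,
            concentration=conc,
            prepared_volume=prepared,
            reagent_mass=conc * prepared * reagent.molecular_weight * 1e-3,
            source_location=f"S{n:03d}",
            suspension=reagent.name in suspensions,
        )
        plan.stocks.append(stock)
        for well, vol in sorted(aliquots):
            plan.transfers.append(Transfer(stock.id, well, vol))

    for sname in sorted(solvent_needs):
        n += 1
        needs = solvent_needs[sname]
        dispensed = sum(v for _, _, v in needs)
        prepared = dispensed * (1.0 + dead_volume_fraction)
        solvent = needs[0][0]
        stock = StockSolution(
            id=f"S{n:03d}",
            reagent=solvent,
            solvent=solvent,
            concentration=0.0,
            prepared_volume=prepared,
            reagent_volume=prepared,
            source_location=f"S{n:03d}",
            neat=True,
        )
        plan.stocks.append(stock)
        for _, well, vol in sorted(needs, key=lambda t: t[1]):
            plan.transfers.append(Transfer(stock.id, well, vol))

    return plan


def human_instructions(plan: DosingPlan) -> str:
    """Render the plan as numbered bench instructions.

    One preparation step per stock (weigh + dissolve, or measure a neat
    liquid), then one distribution step per stock listing its destination
    wells row-major. Ordering is deterministic: stocks by id.
    """
    lines: list[str] = []
    step = 0
    for stock in plan.stocks:
        step += 1
        if stock.neat:
            lines.append(
                f"{step}. Fill vial {stock.id} with {stock.prepared_volume:.1f} uL "
                f"of {stock.reagent.name} (neat)."
            )
        else:
            form = "suspend" if stock.suspension else "dissolve"
            lines.append(
                f"{step}. Weigh {stock.reagent_mass:.2f} mg of "
                f"{stock.reagent.name} into vial {stock.id} and {form} in "
                f"{stock.prepared_volume:.1f} uL {stock.solvent.name} "
                f"({stock.concentration:g} M)."
            )
    for stock in plan.stocks:
        transfers = [t for t in plan.transfers if t.source == stock.id]
        if not transfers:
            continue
        step += 1
        by_vol: dict[float, list[str]] = {}
        for t in sorted(transfers, key=lambda t: t.destination):
            by_vol.setdefault(round(t.volume, 1), []).append(t.destination.label)
        parts = [
            f"{vol:.1f} uL to wells {', '.join(wells)}"
            for vol, wells in sorted(by_vol.items())
        ]
        lines.append(
            f"{step}. Distribute {stock.reagent.name} from vial {stock.id}: "
            + "; ".join(parts)
            + "."
        )
    return "\n".join(lines)


def robot_worklist(plan: DosingPlan) -> list[tuple[str, str, str]]:
    """(source_location, destination label, volume) rows for a liquid handler.

    Volumes are rounded to 0.1 uL and printed with one decimal ("20.0").
    Row order: stock order, then destinations row-major.
    """
    rows: list[tuple[str, str, str]] = []
    for stock in plan.stocks:
        if stock.source_location is None:
            raise DosingError(f"stock {stock.id} has no source location")
        transfers = sorted(
            (t for t in plan.transfers if t.source == stock.id),
            key=lambda t: t.destination,
        )
        for t in transfers:
            rows.append(
                (stock.source_location, t.destination.label, f"{round(t.volume, 1):.1f}")
            )
    return rows


def write_worklist(plan: DosingPlan, path: str | os.PathLike[str]) -> None:
    """Write the worklist CSV (header: source,destination,volume_ul)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source,destination,volume_ul\n")
        for source, dest, vol in robot_worklist(plan):
            fh.write(f"{source},{dest},{vol}\n")
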