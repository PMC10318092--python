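"""The Factors/Grid engine: distribute classed reagents into a factorial array.

Every combination of one reagent per class becomes a reaction well. Classes
of size one (and the solvent) are global: they appear in every reaction and
do not consume a plate axis. The automatic layout places varying classes on
the row and column axes so the plate reads as a multiplexed grid (e.g. four
ligands down the rows, three catalysts x two additive levels across six
columns on a 24-well plate); factor sets that admit no exact axis packing
fall back to a deterministic row-major sequential fill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as iproduct
from typing import Optional, Sequence

from .core_model import (
    CLASS_PRIORITY,
    DoseSpec,
    HteArrayError,
    PlateDesign,
    PlateFormat,
    ReactionSpec,
    Reagent,
    ReagentClass,
    WellAddress,
    class_priority,
    iter_wells,
)


class CapacityError(HteArrayError):
    """The factorial combination count exceeds the available wells."""


class LayoutError(HteArrayError):
    """A layout request is internally inconsistent."""


# Default dosing assumptions applied when a factor set does not specify them.
DEFAULT_SCALE_MMOL = 0.01
DEFAULT_VOLUME_UL = 100.0
DEFAULT_STOCK_M_SUBSTRATE = 0.5
DEFAULT_STOCK_M_CATALYTIC = 0.1

_CATALYTIC = {
    ReagentClass.CATALYST1,
    ReagentClass.CATALYST2,
    ReagentClass.LIGAND1,
    ReagentClass.LIGAND2,
    ReagentClass.ADDITIVE,
}


def default_stock_concentration(cls: ReagentClass) -> float:
    """0.1 M for catalysts/ligands/additives, 0.5 M for everything else."""
    return DEFAULT_STOCK_M_CATALYTIC if cls in _CATALYTIC else DEFAULT_STOCK_M_SUBSTRATE


def default_loading(cls: ReagentClass) -> float:
    """Equivalents charged when the factor set does not specify a loading.

    Catalytic classes default to 20 mol% (0.20 equiv); stoichiometric
    components default to 1.0 equiv.
    """
    return 0.20 if cls in _CATALYTIC else 1.0


@dataclass
class FactorSet:
    """The varying (and global) reagent groups of an experiment.

    ``groups`` maps each reagent class to its candidate reagents;
    ``loadings`` optionally sets the equivalents per class (defaults:
    1.0 equiv for stoichiometric classes, 0.20 for catalytic ones — the
    first class at 1.0 equiv in priority order acts as the limiting
    reagent unless ``limiting_class`` says otherwise); ``replicates``
    duplicates every combination.
    """

    groups: dict[ReagentClass, list[Reagent]]
    replicates: int = 1
    loadings: dict[ReagentClass, float] = field(default_factory=dict)
    stock_concentrations: dict[ReagentClass, float] = field(default_factory=dict)
    scale: float = DEFAULT_SCALE_MMOL  # mmol limiting reagent
    total_volume: float = DEFAULT_VOLUME_UL  # uL
    temperature: float = 25.0
    time: float = 18.0
    limiting_class: Optional[ReagentClass] = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise LayoutError("replicates must be >= 1")
        for cls, members in self.groups.items():
            if not members:
                raise LayoutError(f"class {cls.value} has an empty group")

    def loading_of(self, cls: ReagentClass) -> float:
        return self.loadings.get(cls, default_loading(cls))

    def concentration_of(self, cls: ReagentClass) -> float:
        return self.stock_concentrations.get(cls, default_stock_concentration(cls))

    def solvent(self) -> Reagent:
        members = self.groups.get(ReagentClass.SOLVENT1)
        if not members:
            raise LayoutError("factor set has no Solvent1 entry")
        if len(members) > 1:
            raise LayoutError(
                "multiple Solvent1 entries; varying solvents are not supported"
            )
        return members[0]


def check_capacity(factors: FactorSet, fmt: PlateFormat) -> int:
    """Number of reaction wells the factor set requires; error if > plate size.

    The count is the product of the group sizes (solvent included — a single
    solvent contributes a factor of one) times the replicate count.
    """
    n = factors.replicates
    for members in factors.groups.values():
        n *= len(members)
    if n > fmt.n_wells:
        raise CapacityError(
            f"factor product {n} exceeds the {fmt.n_wells}-well plate"
        )
    return n


def _ordered_classes(factors: FactorSet) -> list[ReagentClass]:
    """Factor classes by the fixed priority list, then input order for ties."""
    order = {cls: i for i, cls in enumerate(factors.groups)}
    return sorted(
        factors.groups, key=lambda c: (class_priority(c), order[c])
    )


def _varying_classes(factors: FactorSet) -> list[ReagentClass]:
    return [
        c
        for c in _ordered_classes(factors)
        if len(factors.groups[c]) > 1 and c is not ReagentClass.SOLVENT1
    ]


def _global_classes(factors: FactorSet) -> list[ReagentClass]:
    return [
        c
        for c in _ordered_classes(factors)
        if len(factors.groups[c]) == 1 and c is not ReagentClass.SOLVENT1
    ]


@dataclass(frozen=True)
class AxisAssignment:
    """Which varying classes index the rows and which the columns."""

    row_classes: tuple[ReagentClass, ...]
    col_classes: tuple[ReagentClass, ...]


def plan_axes(factors: FactorSet, fmt: PlateFormat) -> Optional[AxisAssignment]:
    """Find a deterministic exact row/column packing, or None.

    Classes are taken in priority order and assigned greedily to the row
    axis while the running product stays within ``n_rows``; the remainder
    goes to the columns. If the column product (times replicates) overflows,
    the lowest-priority column classes are pushed back onto the row axis
    ("nested into row blocks") while they fit. Returns None when no exact
    packing exists.
    """
    varying = _varying_classes(factors)
    rows: list[ReagentClass] = []
    cols: list[ReagentClass] = []
    row_prod = 1
    for cls in varying:
        size = len(factors.groups[cls])
        if row_prod * size <= fmt.n_rows:
            rows.append(cls)
            row_prod *= size
        else:
            cols.append(cls)

    def col_prod(cs: Sequence[ReagentClass]) -> int:
        return math.prod(len(factors.groups[c]) for c in cs) * factors.replicates

    while cols and col_prod(cols) > fmt.n_cols:
        moved = cols[-1]
        size = len(factors.groups[moved])
        if row_prod * size <= fmt.n_rows:
            cols = cols[:-1]
            rows.append(moved)
            row_prod *= size
        else:
            return None
    if col_prod(cols) > fmt.n_cols:
        return None
    return AxisAssignment(tuple(rows), tuple(cols))


def _combo_index(
    factors: FactorSet, classes: Sequence[ReagentClass], combo: dict[ReagentClass, Reagent]
) -> int:
    """Mixed-radix index of a combination along the given class axes."""
    idx = 0
    for cls in classes:
        idx = idx * len(factors.groups[cls]) + factors.groups[cls].index(combo[cls])
    return idx


def _build_spec(
    factors: FactorSet, well: WellAddress, combo: dict[ReagentClass, Reagent]
) -> ReactionSpec:
    doses: list[DoseSpec] = []
    limiting_cls = factors.limiting_class
    for cls in _ordered_classes(factors):
        if cls is ReagentClass.SOLVENT1:
            continue
        reagent = combo.get(cls) or factors.groups[cls][0]
        doses.append(
            DoseSpec(
                reagent=reagent,
                loading=factors.loading_of(cls),
                stock_concentration=factors.concentration_of(cls),
                limiting=(cls is limiting_cls),
            )
        )
    return ReactionSpec(
        well=well,
        doses=doses,
        solvent=factors.solvent(),
        scale=factors.scale,
        total_volume=factors.total_volume,
        temperature=factors.temperature,
        time=factors.time,
    )


def _all_combos(factors: FactorSet) -> list[dict[ReagentClass, Reagent]]:
    """Full Cartesian product over varying classes, priority-major order."""
    varying = _varying_classes(factors)
    if not varying:
        return [{}]
    combos = []
    for picks in iproduct(*(factors.groups[c] for c in varying)):
        combos.append(dict(zip(varying, picks)))
    return combos


def auto_layout(
    factors: FactorSet,
    fmt: PlateFormat,
    name: str = "plate",
    allowed_wells: Optional[Sequence[WellAddress]] = None,
) -> PlateDesign:
    """Automatically distribute the factor set into a multiplexed array.

    Each combination of one reagent per class appears exactly ``replicates``
    times; size-one classes appear in every reaction; leftover wells stay
    empty. With an exact axis packing, rows index the row classes and
    columns index the column classes x replicates (replicates in adjacent
    columns); otherwise combinations fill allowed wells row-major, replicate
    copies adjacent. Deterministic given input order.
    """
    n = check_capacity(factors, fmt)
    if allowed_wells is not None:
        allowed = sorted(allowed_wells)
        if n > len(allowed):
            raise CapacityError(
                f"factor product {n} exceeds the {len(allowed)} allowed wells"
            )
    else:
        allowed = None

    design = PlateDesign(name=name, format=fmt)
    combos = _all_combos(factors)
    axes = plan_axes(factors, fmt) if allowed is None else None

    if axes is not None:
        for combo in combos:
            r = _combo_index(factors, axes.row_classes, combo)
            c = _combo_index(factors, axes.col_classes, combo)
            for k in range(factors.replicates):
                well = WellAddress(r, c * factors.replicates + k)
                design.reactions[well] = _build_spec(factors, well, combo)
                if factors.replicates > 1:
                    design.metadata[f"replicate:{well.label}"] = str(k + 1)
        design.metadata["layout"] = "axes"
        design.metadata["row_classes"] = ",".join(c.value for c in axes.row_classes)
        design.metadata["col_classes"] = ",".join(c.value for c in axes.col_classes)
    else:
        fill = allowed if allowed is not None else list(iter_wells(fmt))
        i = 0
        for combo in combos:
            for k in range(factors.replicates):
                well = fill[i]
                i += 1
                design.reactions[well] = _build_spec(factors, well, combo)
                if factors.replicates > 1:
                    design.metadata[f"replicate:{well.label}"] = str(k + 1)
        design.metadata["layout"] = "sequential"
    return design


def manual_assign(
    design: PlateDesign,
    wells: Sequence[WellAddress],
    dose: DoseSpec,
    template: Optional[ReactionSpec] = None,
) -> PlateDesign:
    """Append a dose to each named well in bulk (in place; returns design).

    Empty target wells get a fresh ReactionSpec whose solvent, scale, volume
    and conditions are copied from ``template`` if given, otherwise from the
    design's first occupied well. Adding an identical dose twice is
    idempotent.
    """
    for well in wells:
        if not (
            0 <= well.row < design.format.n_rows
            and 0 <= well.col < design.format.n_cols
        ):
            raise LayoutError(f"well {well.label} out of bounds")
    for well in wells:
        spec = design.reactions.get(well)
        if spec is None:
            proto = template
            if proto is None:
                occupied = design.occupied_wells()
                if not occupied:
                    raise LayoutError(
                        f"well {well.label} is empty and the design has no "
                        "reaction to copy conditions from; pass a template"
                    )
                proto = design.reactions[occupied[0]]
            spec = ReactionSpec(
                well=well,
                doses=[],
                solvent=proto.solvent,
                scale=proto.scale,
                total_volume=proto.total_volume,
                temperature=proto.temperature,
                time=proto.time,
            )
            design.reactions[well] = spec
        if dose not in spec.doses:
            spec.doses.append(dose)
    return design


def remove_dose(
    design: PlateDesign, wells: Sequence[WellAddress], dose: DoseSpec
) -> PlateDesign:
    """Inverse of :func:`manual_assign` for the same dose."""
    for well in wells:
        spec = design.reactions.get(well)
        if spec is not None and dose in spec.doses:
            spec.doses.remove(dose)
    return design


def replicate_expand(design: PlateDesign, n: int) -> PlateDesign:
    """Duplicate every reaction n times into adjacent free wells.

    Returns a new design whose reactions are re-packed row-major so each
    spec's n copies occupy consecutive wells; the replicate index is stored
    in metadata. n=1 is the identity.
    """
    if n < 1:
        raise LayoutError("replicate count must be >= 1")
    if n == 1:
        return design
    occupied = design.occupied_wells()
    if len(occupied) * n > design.format.n_wells:
        raise CapacityError(
            f"{len(occupied)} reactions x {n} replicates exceed the "
            f"{design.format.n_wells}-well plate"
        )
    out = PlateDesign(
        name=design.name, format=design.format, metadata=dict(design.metadata)
    )
    fill = list(iter_wells(design.format))
    i = 0
    for well in occupied:
        spec = design.reactions[well]
        for k in range(n):
            target = fill[i]
            i += 1
            out.reactions[target] = ReactionSpec(
                well=target,
                doses=list(spec.doses),
                solvent=spec.solvent,
                scale=spec.scale,
                total_volume=spec.total_volume,
                temperature=spec.temperature,
                time=spec.time,
            )
            out.metadata[f"replicate:{target.label}"] = str(k + 1)
            out.metadata[f"parent:{target.label}"] = well.label
    return out
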