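"""Parent/daughter plate mapping for ultraHTE.

A 1536-well reaction plate is stamped into four 384-well daughter plates
for analysis by the standard interleaved (row-parity / column-parity)
quadrant convention: daughter d = 2*(row mod 2) + (col mod 2) + 1, daughter
coordinates (row div 2, col div 2). Daughter plates reserve whole control
columns (default 1, 2, 23 and 24) for the assay's positive/negative
controls, so the corresponding parent wells must stay empty of reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_model import (
    HteArrayError,
    PlateDesign,
    PlateFormat,
    ReactionSpec,
    Reagent,
    WellAddress,
    iter_wells,
)
from .layout import CapacityError, FactorSet, auto_layout
from .dosing import Transfer

PARENT_FORMAT = PlateFormat(1536)
DAUGHTER_FORMAT = PlateFormat(384)

#: Outermost column pairs of each 384-well daughter, 1-based.
DEFAULT_CONTROL_COLUMNS = (1, 2, 23, 24)


class PlateMapError(HteArrayError):
    """A parent/daughter mapping request is invalid."""


@dataclass(frozen=True)
class ControlSpec:
    """Which daughter-plate columns are reserved for assay controls."""

    columns: tuple[int, ...] = DEFAULT_CONTROL_COLUMNS
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.columns:
            if not 1 <= c <= DAUGHTER_FORMAT.n_cols:
                raise PlateMapError(f"control column {c} outside 1..24")
        if not self.labels:
            # positive/negative roles alternate across the reserved columns
            roles = {}
            for i, c in enumerate(sorted(self.columns)):
                roles[c] = "positive" if i % 2 == 0 else "negative"
            object.__setattr__(self, "labels", roles)


def quadrant_of(well: WellAddress) -> tuple[int, WellAddress]:
    """Map a 1536-well parent address to (daughter 1-4, daughter address).

    Interleaved stamping: neighbouring parent wells go to different
    daughters; the map is a bijection onto 4 x 384 daughter wells.
    """
    if not (0 <= well.row < PARENT_FORMAT.n_rows and 0 <= well.col < PARENT_FORMAT.n_cols):
        raise PlateMapError(f"well {well.label} out of bounds for a 1536-well plate")
    daughter = 2 * (well.row % 2) + (well.col % 2) + 1
    return daughter, WellAddress(well.row // 2, well.col // 2)


def parent_of(daughter: int, well: WellAddress) -> WellAddress:
    """Inverse of :func:`quadrant_of`."""
    if not 1 <= daughter <= 4:
        raise PlateMapError(f"daughter index {daughter} outside 1..4")
    if not (
        0 <= well.row < DAUGHTER_FORMAT.n_rows
        and 0 <= well.col < DAUGHTER_FORMAT.n_cols
    ):
        raise PlateMapError(f"well {well.label} out of bounds for a 384-well plate")
    return WellAddress(2 * well.row + (daughter - 1) // 2, 2 * well.col + (daughter - 1) % 2)


@dataclass(frozen=True)
class QuadrantMap:
    """The full 1536 -> 4 x 384 bijection, materialized."""

    parent: PlateFormat = PARENT_FORMAT
    daughter: PlateFormat = DAUGHTER_FORMAT

    def mapping(self) -> dict[WellAddress, tuple[int, WellAddress]]:
        return {w: quadrant_of(w) for w in iter_wells(self.parent)}


def reserved_parent_wells(controls: ControlSpec) -> list[WellAddress]:
    """Parent wells that land in a control column of any daughter.

    Count = |columns| x 16 rows x 4 daughters.
    """
    reserved = []
    for d in range(1, 5):
        for c in controls.columns:
            for r in range(DAUGHTER_FORMAT.n_rows):
                reserved.append(parent_of(d, WellAddress(r, c - 1)))
    return sorted(set(reserved))


def plan_split(
    design: PlateDesign, controls: ControlSpec = ControlSpec()
) -> tuple[list[PlateDesign], list[WellAddress]]:
    """Split a 1536-well design into its four 384-well daughters.

    Each daughter receives its quadrant's reactions; control columns are
    labelled by role in daughter metadata and must hold no reactions.
    Returns (daughters, reserved parent wells). Daughter metadata records
    each well's parent label so results re-join unambiguously.
    """
    if design.format != PARENT_FORMAT:
        raise PlateMapError("plan_split requires a 1536-well design")
    reserved = set(reserved_parent_wells(controls))
    daughters = [
        PlateDesign(name=f"{design.name}-D{d}", format=DAUGHTER_FORMAT)
        for d in range(1, 5)
    ]
    for d in daughters:
        for col, role in sorted(controls.labels.items()):
            d.metadata[f"control_column:{col}"] = role
    for well in design.occupied_wells():
        if well in reserved:
            raise PlateMapError(
                f"reaction in well {well.label} occupies a control-reserved well"
            )
        d, dwell = quadrant_of(well)
        spec = design.reactions[well]
        daughters[d - 1].reactions[dwell] = ReactionSpec(
            well=dwell,
            doses=list(spec.doses),
            solvent=spec.solvent,
            scale=spec.scale,
            total_volume=spec.total_volume,
            temperature=spec.temperature,
            time=spec.time,
        )
        daughters[d - 1].metadata[f"parent:{dwell.label}"] = well.label
    return daughters, sorted(reserved)


def layout_with_controls(
    factors: FactorSet,
    controls: ControlSpec = ControlSpec(),
    name: str = "plate",
) -> PlateDesign:
    """Auto-layout on a 1536-well plate, avoiding control-reserved wells.

    With no reserved columns this is exactly plain auto_layout; otherwise
    the factorial combinations fill the non-reserved wells row-major so
    that plan_split of the result always succeeds.
    """
    if not controls.columns:
        return auto_layout(factors, PARENT_FORMAT, name=name)
    reserved = set(reserved_parent_wells(controls))
    allowed = [w for w in iter_wells(PARENT_FORMAT) if w not in reserved]
    design = auto_layout(factors, PARENT_FORMAT, name=name, allowed_wells=allowed)
    design.metadata["control_columns"] = ",".join(str(c) for c in controls.columns)
    return design


def analytical_plate(
    design: PlateDesign,
    aliquot_volume: float,
    diluent_volume: float,
    internal_standard: Reagent,
    is_equivalents: float = 1.0,
) -> tuple[PlateDesign, list[Transfer]]:
    """Derive the diluted analytical daughter of a reaction plate.

    An aliquot of each reaction is transferred 1:1 (same format) into a
    well holding the diluent and the internal standard. The dilution factor
    (aliquot + diluent) / aliquot and the IS amount (``is_equivalents`` x
    scale, in mmol) are recorded per plate / per well in metadata.
    """
    if aliquot_volume <= 0:
        raise PlateMapError("aliquot volume must be > 0")
    if diluent_volume < 0:
        raise PlateMapError("diluent volume must be >= 0")
    out = PlateDesign(
        name=f"{design.name}-analytical",
        format=design.format,
        metadata=dict(design.metadata),
    )
    dilution = (aliquot_volume + diluent_volume) / aliquot_volume
    out.metadata["dilution_factor"] = repr(dilution)
    out.metadata["internal_standard"] = internal_standard.name
    transfers: list[Transfer] = []
    for well in design.occupied_wells():
        spec = design.reactions[well]
        if aliquot_volume > spec.total_volume:
            raise PlateMapError(
                f"well {well.label}: aliquot {aliquot_volume} uL exceeds the "
                f"{spec.total_volume} uL reaction volume"
            )
        out.reactions[well] = ReactionSpec(
            well=well,
            doses=list(spec.doses),
            solvent=spec.solvent,
            scale=spec.scale,
            total_volume=aliquot_volume + diluent_volume,
            temperature=spec.temperature,
            time=spec.time,
        )
        out.metadata[f"parent:{well.label}"] = well.label
        out.metadata[f"is_mmol:{well.label}"] = repr(is_equivalents * spec.scale)
        transfers.append(Transfer(well.label, well, aliquot_volume))
    return out, transfers
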