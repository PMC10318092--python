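"""Plate geometry, well addressing and the shared domain types.

A wellplate is a rectangular grid of reaction vessels; the four supported
densities are 24 (4x6), 96 (8x12), 384 (16x24) and 1536 (32x48) wells.
Coordinates are 0-based internally; printed labels use letter rows
(A..Z, AA..AF) and 1-based column numbers, e.g. "B3" or "AF48".
Well iteration order is row-major throughout the package.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence


class HteArrayError(Exception):
    """Base class for all errors raised by this package."""


class PlateGeometryError(HteArrayError):
    """A well address or plate format is invalid."""


# ---------------------------------------------------------------------------
# Plate formats
# ---------------------------------------------------------------------------

#: (n_rows, n_cols) for each supported plate density.
PLATE_SHAPES: Mapping[int, tuple[int, int]] = {
    24: (4, 6),
    96: (8, 12),
    384: (16, 24),
    1536: (32, 48),
}


@dataclass(frozen=True)
class PlateFormat:
    """One of the four standard rectangular wellplate densities."""

    n_wells: int

    def __post_init__(self) -> None:
        if self.n_wells not in PLATE_SHAPES:
            raise PlateGeometryError(
                f"unsupported plate size {self.n_wells}; "
                f"must be one of {sorted(PLATE_SHAPES)}"
            )

    @property
    def n_rows(self) -> int:
        return PLATE_SHAPES[self.n_wells][0]

    @property
    def n_cols(self) -> int:
        return PLATE_SHAPES[self.n_wells][1]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.n_wells}-well"


# ---------------------------------------------------------------------------
# Well addressing
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^([A-Z]+)([0-9]+)$")


@dataclass(frozen=True, order=True)
class WellAddress:
    """0-based (row, col) position on a plate."""

    row: int
    col: int

    @property
    def label(self) -> str:
        return format_well_label(self)


def _row_letters(row: int) -> str:
    """0-based row index -> bijective base-26 letters (A..Z, AA..AF, ...)."""
    letters = ""
    n = row + 1
    while n > 0:
        n, rem = divmod(n - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def _letters_to_row(letters: str) -> int:
    n = 0
    for ch in letters:
        n = n * 26 + (ord(ch) - ord("A") + 1)
    return n - 1


def format_well_label(well: WellAddress) -> str:
    """Render a 0-based address as a printed label, e.g. (1, 2) -> "B3"."""
    return f"{_row_letters(well.row)}{well.col + 1}"


def parse_well_label(label: str, fmt: PlateFormat) -> WellAddress:
    """Parse a printed label ("B3", "AF48") into a 0-based address.

    Raises :class:`PlateGeometryError` for malformed labels or addresses
    outside the plate bounds.
    """
    m = _LABEL_RE.match(label.strip().upper())
    if not m:
        raise PlateGeometryError(f"malformed well label: {label!r}")
    row = _letters_to_row(m.group(1))
    col = int(m.group(2)) - 1
    if not (0 <= row < fmt.n_rows and 0 <= col < fmt.n_cols):
        raise PlateGeometryError(
            f"well {label!r} out of bounds for a {fmt.n_wells}-well plate"
        )
    return WellAddress(row, col)


def enumerate_wells(fmt: PlateFormat) -> list[WellAddress]:
    """All wells of the plate in row-major order (A1, A2, ..., last row/col)."""
    return [
        WellAddress(r, c) for r in range(fmt.n_rows) for c in range(fmt.n_cols)
    ]


def iter_wells(fmt: PlateFormat) -> Iterator[WellAddress]:
    for r in range(fmt.n_rows):
        for c in range(fmt.n_cols):
            yield WellAddress(r, c)


# ---------------------------------------------------------------------------
# Reagents
# ---------------------------------------------------------------------------


class ReagentClass(enum.Enum):
    """The closed set of reagent role labels used to multiplex plate axes."""

    ELECTROPHILE = "Electrophile"
    NUCLEOPHILE = "Nucleophile"
    CATALYST1 = "Catalyst1"
    CATALYST2 = "Catalyst2"
    LIGAND1 = "Ligand1"
    LIGAND2 = "Ligand2"
    BASE_ACID = "Base/Acid"
    REDUCTANT_OXIDANT = "Reductant/Oxidant"
    SOLVENT1 = "Solvent1"
    ADDITIVE = "Additive"
    OTHER = "Other"

    @classmethod
    def from_label(cls, label: str) -> "ReagentClass":
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(
            f"unknown reagent class {label!r}; "
            f"must be one of {[m.value for m in cls]}"
        )

    @property
    def slug(self) -> str:
        """Lower-case identifier safe for column names (base_acid, ...)."""
        return self.value.lower().replace("/", "_")


#: Fixed priority used to order classes when assigning plate axes and when
#: serializing doses: catalytic components vary first, substrates last.
CLASS_PRIORITY: tuple[ReagentClass, ...] = (
    ReagentClass.LIGAND1,
    ReagentClass.CATALYST1,
    ReagentClass.CATALYST2,
    ReagentClass.LIGAND2,
    ReagentClass.ADDITIVE,
    ReagentClass.BASE_ACID,
    ReagentClass.REDUCTANT_OXIDANT,
    ReagentClass.ELECTROPHILE,
    ReagentClass.NUCLEOPHILE,
    ReagentClass.OTHER,
    ReagentClass.SOLVENT1,
)


def class_priority(cls: ReagentClass) -> int:
    return CLASS_PRIORITY.index(cls)


@dataclass(frozen=True)
class Reagent:
    """An inventory entry: a chemical with its physical constants and role.

    molecular_weight is in g/mol, density (optional) in g/mL. ``colour`` is
    a hex string used in plate renderings.
    """

    name: str
    molecular_weight: float
    reagent_class: ReagentClass
    smiles: Optional[str] = None
    density: Optional[float] = None
    cas: Optional[str] = None
    inventory_location: Optional[str] = None
    colour: Optional[str] = None


# ---------------------------------------------------------------------------
# Reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseSpec:
    """One reagent charged to a well.

    ``loading`` is dimensionless equivalents relative to the limiting
    reagent; mol% is expressed as fractional equivalents (20 mol% = 0.20).
    ``stock_concentration`` is the molarity (mol/L) of the stock solution
    the reagent is dosed from.
    """

    reagent: Reagent
    loading: float
    stock_concentration: float
    limiting: bool = False

    def __post_init__(self) -> None:
        if self.loading <= 0:
            raise ValueError("loading must be > 0")
        if self.stock_concentration <= 0:
            raise ValueError("stock_concentration must be > 0")


@dataclass
class ReactionSpec:
    """A single well's reaction: doses, solvent, scale and conditions.

    ``scale`` is mmol of the limiting reagent; ``total_volume`` is the final
    reaction volume in uL, reached by topping up with solvent after dosing.
    """

    well: WellAddress
    doses: list[DoseSpec]
    solvent: Reagent
    scale: float  # mmol of limiting reagent
    total_volume: float  # uL
    temperature: float = 25.0  # degC
    time: float = 18.0  # h

    def limiting_dose(self) -> DoseSpec:
        tagged = [d for d in self.doses if d.limiting]
        if len(tagged) == 1:
            return tagged[0]
        if len(tagged) > 1:
            raise ValueError(f"well {self.well.label}: multiple limiting doses")
        unit = [d for d in self.doses if d.loading == 1.0]
        if unit:
            return unit[0]
        raise ValueError(
            f"well {self.well.label}: no limiting reagent (no dose tagged "
            "limiting and none at loading 1.0)"
        )


@dataclass
class PlateDesign:
    """A named plate format plus per-well reaction specifications.

    ``reactions`` is a partial mapping: wells may be empty. This is the
    central object of an experiment; every downstream stage (dosing,
    splitting, analysis, reporting) consumes it.
    """

    name: str
    format: PlateFormat
    reactions: dict[WellAddress, ReactionSpec] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for well in self.reactions:
            if not (
                0 <= well.row < self.format.n_rows
                and 0 <= well.col < self.format.n_cols
            ):
                raise PlateGeometryError(
                    f"well {well.label} out of bounds for {self.format}"
                )

    def occupied_wells(self) -> list[WellAddress]:
        """Occupied wells in row-major order."""
        return sorted(self.reactions)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)


# ---------------------------------------------------------------------------
# Colours
# ---------------------------------------------------------------------------

#: 24-entry qualitative palette (tab20 + 4 extras), cycled with a shade shift.
_PALETTE: tuple[str, ...] = (
    "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c", "#98df8a",
    "#d62728", "#ff9896", "#9467bd", "#c5b0d5", "#8c564b", "#c49c94",
    "#e377c2", "#f7b6d2", "#7f7f7f", "#c7c7c7", "#bcbd22", "#dbdb8d",
    "#17becf", "#9edae5", "#393b79", "#637939", "#8c6d31", "#843c39",
)


def _shade(hex_colour: str, cycle: int) -> str:
    """Darken a hex colour by 15% per palette cycle so repeats stay distinct."""
    if cycle == 0:
        return hex_colour
    f = 0.85**cycle
    r = int(hex_colour[1:3], 16)
    g = int(hex_colour[3:5], 16)
    b = int(hex_colour[5:7], 16)
    return f"#{int(r * f):02x}{int(g * f):02x}{int(b * f):02x}"


def assign_colours(reagents: Sequence[Reagent]) -> dict[Reagent, str]:
    """Deterministically map reagents to distinct display colours.

    The fixed 24-colour palette is cycled; each further cycle darkens the
    base colour so reagent 25 gets a shaded copy of colour 1. Reagents seen
    more than once keep their first colour.
    """
    if not reagents:
        raise ValueError("assign_colours requires a non-empty reagent list")
    mapping: dict[Reagent, str] = {}
    i = 0
    for reagent in reagents:
        if reagent in mapping:
            continue
        cycle, idx = divmod(i, len(_PALETTE))
        mapping[reagent] = _shade(_PALETTE[idx], cycle)
        i += 1
    return mapping
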