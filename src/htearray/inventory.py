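"""Chemical-inventory I/O and validation.

The inventory CSV dialect is fixed here: UTF-8, comma-delimited, RFC-4180
quoting, with the exact ordered header

    name,smiles,cas,molecular_weight,density,reagent_class,inventory_location,colour

Missing optional fields are empty strings. ``reagent_class`` must be one of
the eleven role labels (Electrophile, Nucleophile, Catalyst1, Catalyst2,
Ligand1, Ligand2, Base/Acid, Reductant/Oxidant, Solvent1, Additive, Other).
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

from .core_model import HteArrayError, Reagent, ReagentClass

RDLogger.DisableLog("rdApp.*")  # SMILES issues are reported, not printed

INVENTORY_COLUMNS = (
    "name",
    "smiles",
    "cas",
    "molecular_weight",
    "density",
    "reagent_class",
    "inventory_location",
    "colour",
)

REQUIRED_COLUMNS = ("name", "molecular_weight", "reagent_class")


class InventoryError(HteArrayError):
    """An inventory file or reagent record is invalid."""


@dataclass
class Inventory:
    """A list of reagents with unique names, tagged with its source."""

    reagents: list[Reagent] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        names = [r.name for r in self.reagents]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise InventoryError(f"duplicate reagent names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.reagents)

    def __iter__(self):
        return iter(self.reagents)

    def by_class(self, cls: ReagentClass) -> list[Reagent]:
        return [r for r in self.reagents if r.reagent_class is cls]

    def get(self, name: str) -> Reagent:
        for r in self.reagents:
            if r.name == name:
                return r
        raise KeyError(name)


def _parse_row(row: dict[str, str], lineno: int) -> Reagent:
    name = row.get("name", "").strip()
    if not name:
        raise InventoryError(f"line {lineno}: empty reagent name")
    mw_text = row.get("molecular_weight", "").strip()
    try:
        mw = float(mw_text)
    except ValueError:
        raise InventoryError(
            f"line {lineno}: non-numeric molecular_weight {mw_text!r}"
        ) from None
    cls_text = row.get("reagent_class", "").strip()
    try:
        cls = ReagentClass.from_label(cls_text)
    except ValueError:
        raise InventoryError(
            f"line {lineno}: unknown reagent class {cls_text!r}"
        ) from None
    density_text = row.get("density", "").strip()
    density = float(density_text) if density_text else None
    reagent = Reagent(
        name=name,
        molecular_weight=mw,
        reagent_class=cls,
        smiles=row.get("smiles", "").strip() or None,
        density=density,
        cas=row.get("cas", "").strip() or None,
        inventory_location=row.get("inventory_location", "").strip() or None,
        colour=row.get("colour", "").strip() or None,
    )
    if mw <= 0:
        raise InventoryError(f"line {lineno}: molecular_weight must be > 0")
    if density is not None and density <= 0:
        raise InventoryError(f"line {lineno}: density must be > 0")
    return reagent


def read_inventory(path: str | os.PathLike[str]) -> Inventory:
    """Read an inventory CSV, validating every row.

    Rows with an unknown reagent class, a non-numeric molecular weight or a
    missing required field raise :class:`InventoryError` naming the line.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        return _read_inventory_stream(fh, source=str(path))


def _read_inventory_stream(fh, source: str) -> Inventory:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise InventoryError(f"{source}: empty file, no header row")
    missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise InventoryError(f"{source}: missing required column(s) {missing}")
    reagents = [_parse_row(row, lineno) for lineno, row in enumerate(reader, 2)]
    return Inventory(reagents=reagents, source=source)


def write_inventory(inv: Inventory, path: str | os.PathLike[str]) -> None:
    """Write the inventory CSV; read_inventory round-trips all fields."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        _write_inventory_stream(inv, fh)


def _write_inventory_stream(inv: Inventory, fh) -> None:
    writer = csv.writer(fh)
    writer.writerow(INVENTORY_COLUMNS)
    for r in inv.reagents:
        writer.writerow(
            [
                r.name,
                r.smiles or "",
                r.cas or "",
                repr(r.molecular_weight),
                repr(r.density) if r.density is not None else "",
                r.reagent_class.value,
                r.inventory_location or "",
                r.colour or "",
            ]
        )


def inventory_to_csv(inv: Inventory) -> str:
    buf = io.StringIO()
    _write_inventory_stream(inv, buf)
    return buf.getvalue()


def validate_reagent(r: Reagent) -> list[str]:
    """Return a list of human-readable issues; empty iff the reagent is valid.

    The SMILES check is syntactic only (RDKit parse), and runs only when a
    SMILES string is present.
    """
    issues: list[str] = []
    if not r.name:
        issues.append("name must be non-empty")
    if r.molecular_weight <= 0:
        issues.append("molecular_weight must be > 0")
    if r.density is not None and r.density <= 0:
        issues.append("density must be > 0")
    if not isinstance(r.reagent_class, ReagentClass):
        issues.append("reagent_class must be one of the defined class set")
    if r.smiles:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:
            issues.append(f"SMILES does not parse: {r.smiles!r}")
    return issues
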