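"""Standardized experiment records, collation, visual matrices, exports.

The one-row-per-reaction output CSV is the package's interchange format:

    plate,well,<class>_name,<class>_smiles,<class>_loading,<class>_molarity,...
    solvent,scale_mmol,volume_ul,temperature_c,time_h,<channel columns>

Class prefixes are slugs of the reagent-class labels (ligand1, catalyst1,
base_acid, ...), emitted in class-priority order for the classes actually
populated. Per-plate files concatenate trivially into collated datasets.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.manifold import TSNE

from .analysis import AnalysisError, ResultRecord
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
    parse_well_label,
)

_FIXED_COLUMNS = ("solvent", "scale_mmol", "volume_ul", "temperature_c", "time_h")


class ReportingError(HteArrayError):
    """An experiment record cannot be compiled, parsed or collated."""


@dataclass
class ExperimentRecord:
    """One-row-per-reaction join of a plate design and its results."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | os.PathLike[str]) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class CollatedDataset:
    """Union of experiment-record rows across plates, with provenance."""

    table: pd.DataFrame  # includes a 'provenance' column

    def __len__(self) -> int:
        return len(self.table)


def _populated_classes(design: PlateDesign) -> list[ReagentClass]:
    present = {
        d.reagent.reagent_class
        for spec in design.reactions.values()
        for d in spec.doses
    }
    return sorted(present, key=class_priority)


def _doses_by_class(spec: ReactionSpec) -> dict[ReagentClass, list[DoseSpec]]:
    out: dict[ReagentClass, list[DoseSpec]] = {}
    for d in spec.doses:
        out.setdefault(d.reagent.reagent_class, []).append(d)
    return out


def compile_output(
    design: PlateDesign, records: Sequence[ResultRecord] = ()
) -> ExperimentRecord:
    """Join the design with well-keyed results into the standard table.

    Rows are emitted row-major over occupied wells; wells without results
    carry empty output cells. A result keyed to an unoccupied well raises.
    Wells carrying several reagents of one class join their fields with ";".
    """
    by_well: dict[WellAddress, ResultRecord] = {}
    for r in records:
        if r.well not in design.reactions:
            raise ReportingError(f"result for unoccupied well {r.well.label}")
        if r.well in by_well:
            raise ReportingError(f"duplicate result for well {r.well.label}")
        by_well[r.well] = r

    classes = _populated_classes(design)
    channels = sorted({ch for r in records for ch in r.channels})
    columns = ["plate", "well"]
    for cls in classes:
        columns += [
            f"{cls.slug}_name",
            f"{cls.slug}_smiles",
            f"{cls.slug}_loading",
            f"{cls.slug}_molarity",
        ]
    columns += list(_FIXED_COLUMNS) + channels

    rows = []
    for well in design.occupied_wells():
        spec = design.reactions[well]
        row: dict[str, object] = {"plate": design.name, "well": well.label}
        per_class = _doses_by_class(spec)
        for cls in classes:
            doses = per_class.get(cls, [])
            row[f"{cls.slug}_name"] = ";".join(d.reagent.name for d in doses)
            row[f"{cls.slug}_smiles"] = ";".join(
                d.reagent.smiles or "" for d in doses
            )
            row[f"{cls.slug}_loading"] = ";".join(repr(d.loading) for d in doses)
            row[f"{cls.slug}_molarity"] = ";".join(
                repr(d.stock_concentration) for d in doses
            )
        row["solvent"] = spec.solvent.name
        row["scale_mmol"] = repr(spec.scale)
        row["volume_ul"] = repr(spec.total_volume)
        row["temperature_c"] = repr(spec.temperature)
        row["time_h"] = repr(spec.time)
        rec = by_well.get(well)
        for ch in channels:
            v = rec.get(ch) if rec is not None else None
            row[ch] = "" if v is None else repr(v)
        rows.append(row)
    table = pd.DataFrame(rows, columns=columns).fillna("")
    return ExperimentRecord(table=table)


def read_output(path: str | os.PathLike[str]) -> ExperimentRecord:
    """Read an experiment-record CSV back, cells as written (strings)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "plate" not in df.columns or "well" not in df.columns:
        raise ReportingError(f"{path}: not an experiment record (plate/well missing)")
    return ExperimentRecord(table=df)


def collate(paths: Sequence[str | os.PathLike[str]]) -> CollatedDataset:
    """Concatenate per-plate outputs into one dataset with provenance.

    The schema is the column union; cells missing from a file stay empty.
    Row count is the sum of the per-plate counts.
    """
    frames = []
    for path in paths:
        rec = read_output(path)
        df = rec.table.copy()
        df.insert(0, "provenance", os.path.basename(os.fspath(path)))
        frames.append(df)
    if not frames:
        raise ReportingError("no files to collate")
    table = pd.concat(frames, ignore_index=True, sort=False).fillna("")
    return CollatedDataset(table=table)


def heatmap_matrix(
    design: PlateDesign,
    records: Sequence[ResultRecord],
    channel: str,
) -> np.ndarray:
    """n_rows x n_cols matrix of a channel; empty/missing wells are NaN."""
    if not any(r.get(channel) is not None for r in records):
        raise ReportingError(f"channel {channel!r} absent from the results")
    mat = np.full((design.format.n_rows, design.format.n_cols), np.nan)
    for r in records:
        if r.well not in design.reactions:
            raise ReportingError(f"result for unoccupied well {r.well.label}")
        v = r.get(channel)
        if v is not None:
            mat[r.well.row, r.well.col] = v
    return mat


def render_heatmap(matrix: np.ndarray, path: str, title: str = "") -> None:
    """Optional thin rendering layer over :func:`heatmap_matrix`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(matrix, cmap="viridis")
    fig.colorbar(im, ax=ax)
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# Chemical-space embedding
# ---------------------------------------------------------------------------


def tsne_embed(
    dataset: CollatedDataset,
    smiles_column: str,
    colour_channel: str,
    seed: int,
    perplexity: float = 5.0,
) -> list[tuple[float, float, float]]:
    """2-D tSNE of unique product structures, coloured by mean outcome.

    Each unique SMILES in ``smiles_column`` is fingerprinted (2048-bit
    Morgan, radius 2) and embedded; its colour value is the mean of
    ``colour_channel`` over the rows carrying that product. Unparseable
    SMILES are skipped with a warning; fewer than 3 unique products raise.
    Output is deterministic for a fixed seed, and points are ordered by
    SMILES string so input row order cannot permute the result.
    """
    import warnings

    df = dataset.table
    if smiles_column not in df.columns:
        raise ReportingError(f"column {smiles_column!r} missing")
    if colour_channel not in df.columns:
        raise ReportingError(f"column {colour_channel!r} missing")

    values: dict[str, list[float]] = {}
    for smiles, cell in zip(df[smiles_column], df[colour_channel]):
        s = str(smiles).strip()
        c = str(cell).strip()
        if not s or not c:
            continue
        values.setdefault(s, []).append(float(c))

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    fps, colours = [], []
    for smiles in sorted(values):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            warnings.warn(f"skipping unparseable SMILES {smiles!r}")
            continue
        fps.append(np.array(gen.GetFingerprint(mol), dtype=float))
        colours.append(float(np.mean(values[smiles])))
    if len(fps) < 3:
        raise ReportingError("need >= 3 unique parseable products for tSNE")

    X = np.vstack(fps)
    tsne = TSNE(
        n_components=2,
        perplexity=min(perplexity, len(fps) - 1),
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(X)
    return [
        (float(x), float(y), c) for (x, y), c in zip(coords, colours)
    ]


# ---------------------------------------------------------------------------
# JSON export and design serialization
# ---------------------------------------------------------------------------


def _reagent_to_dict(r: Reagent) -> dict:
    return {
        "name": r.name,
        "smiles": r.smiles,
        "cas": r.cas,
        "molecular_weight": r.molecular_weight,
        "density": r.density,
        "reagent_class": r.reagent_class.value,
        "inventory_location": r.inventory_location,
        "colour": r.colour,
    }


def _reagent_from_dict(d: dict) -> Reagent:
    return Reagent(
        name=d["name"],
        molecular_weight=d["molecular_weight"],
        reagent_class=ReagentClass.from_label(d["reagent_class"]),
        smiles=d.get("smiles"),
        density=d.get("density"),
        cas=d.get("cas"),
        inventory_location=d.get("inventory_location"),
        colour=d.get("colour"),
    )


def export_json(
    design: PlateDesign, records: Sequence[ResultRecord] = ()
) -> dict:
    """Generic nested experiment record (experiment -> reactions).

    Each reaction entry lists its inputs in class-priority order with
    loadings and molarities, its conditions, and its outcome channels —
    enough structure for downstream ORD/XDL conversion scripts. Key order
    is stable; json round-trips exactly.
    """
    by_well = {r.well: r for r in records}
    reactions = []
    for well in design.occupied_wells():
        spec = design.reactions[well]
        doses = sorted(
            spec.doses, key=lambda d: class_priority(d.reagent.reagent_class)
        )
        rec = by_well.get(well)
        reactions.append(
            {
                "well": well.label,
                "inputs": [
                    {
                        "name": d.reagent.name,
                        "smiles": d.reagent.smiles,
                        "reagent_class": d.reagent.reagent_class.value,
                        "loading_equiv": d.loading,
                        "stock_molarity": d.stock_concentration,
                    }
                    for d in doses
                ],
                "solvent": spec.solvent.name,
                "conditions": {
                    "scale_mmol": spec.scale,
                    "volume_ul": spec.total_volume,
                    "temperature_c": spec.temperature,
                    "time_h": spec.time,
                },
                "outcomes": dict(sorted(rec.channels.items())) if rec else {},
            }
        )
    return {
        "experiment": {
            "name": design.name,
            "plate_format": design.format.n_wells,
            "metadata": dict(sorted(design.metadata.items())),
        },
        "reactions": reactions,
    }


def design_to_dict(design: PlateDesign) -> dict:
    """Full lossless serialization of a plate design (for files and CLI)."""
    return {
        "name": design.name,
        "plate_format": design.format.n_wells,
        "metadata": dict(sorted(design.metadata.items())),
        "reactions": [
            {
                "well": well.label,
                "doses": [
                    {
                        "reagent": _reagent_to_dict(d.reagent),
                        "loading": d.loading,
                        "stock_concentration": d.stock_concentration,
                        "limiting": d.limiting,
                    }
                    for d in design.reactions[well].doses
                ],
                "solvent": _reagent_to_dict(design.reactions[well].solvent),
                "scale_mmol": design.reactions[well].scale,
                "volume_ul": design.reactions[well].total_volume,
                "temperature_c": design.reactions[well].temperature,
                "time_h": design.reactions[well].time,
            }
            for well in design.occupied_wells()
        ],
    }


def design_from_dict(d: dict) -> PlateDesign:
    fmt = PlateFormat(d["plate_format"])
    design = PlateDesign(
        name=d["name"], format=fmt, metadata=dict(d.get("metadata", {}))
    )
    for entry in d["reactions"]:
        well = parse_well_label(entry["well"], fmt)
        design.reactions[well] = ReactionSpec(
            well=well,
            doses=[
                DoseSpec(
                    reagent=_reagent_from_dict(x["reagent"]),
                    loading=x["loading"],
                    stock_concentration=x["stock_concentration"],
                    limiting=x.get("limiting", False),
                )
                for x in entry["doses"]
            ],
            solvent=_reagent_from_dict(entry["solvent"]),
            scale=entry["scale_mmol"],
            total_volume=entry["volume_ul"],
            temperature=entry["temperature_c"],
            time=entry["time_h"],
        )
    return design


def save_design(design: PlateDesign, path: str | os.PathLike[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(design_to_dict(design), fh, indent=2)


def load_design(path: str | os.PathLike[str]) -> PlateDesign:
    with open(path, encoding="utf-8") as fh:
        return design_from_dict(json.load(fh))
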