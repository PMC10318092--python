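"""Seeded synthetic-data generators: inventories, results and bioassays.

Everything needed to exercise the full workflow is generated in memory with
an explicit seed — no global random state, no external files. The reaction
outcome model is deliberately simple and additive: each well's yield is a
base level plus the planted effect of every reagent it contains plus
Gaussian noise, floored at zero. That is enough to test ranking, replicate
agreement and the analytics plumbing; it does not attempt mechanistic
chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .analysis import AssayControls, ResultRecord
from .core_model import PlateDesign, Reagent, ReagentClass, assign_colours
from .inventory import Inventory

#: Valid building-block SMILES cycled when synthesizing reagent structures,
#: so fingerprinting in embedding tests never fails.
_SMILES_POOL: tuple[str, ...] = (
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "C1CCCCC1", "C1CCNCC1",
    "c1ccc(Cl)cc1", "c1ccc(Br)cc1", "c1ccc(F)cc1", "c1ccc(C)cc1",
    "c1ccc(OC)cc1", "c1ccc(N)cc1", "c1ccc(C#N)cc1", "c1ccc(C(F)(F)F)cc1",
    "CC(C)O", "CCOC(C)=O", "CS(C)=O", "CC#N", "C1CCOC1",
    "OC(=O)c1ccccc1", "NCc1ccccc1", "O=Cc1ccccc1", "CC(=O)c1ccccc1",
    "c1cnc2[nH]ccc2c1", "c1csc(c1)C", "c1cc(oc1)C", "CCN(CC)CC",
)

#: Internal-standard area emitted by the synthetic analytics; the product
#: area is yield/100 x this, so ratio x 100 recovers the yield.
REFERENCE_AREA = 1000.0


@dataclass
class TruthModel:
    """Planted ground truth for synthetic reaction outcomes (percent yield)."""

    base_yield: float = 40.0
    effects: dict[tuple[ReagentClass, str], float] = field(default_factory=dict)
    noise_sd: float = 3.0
    seed: int = 0


@dataclass
class AssaySimSpec:
    """Parameters of the simulated direct-to-biology plate assay.

    ``hit_relation`` maps percent yield to percent inhibition and must be
    monotone non-decreasing; control wells draw from Normal(mean, sd) for
    the stated positive/negative means.
    """

    control_means: tuple[float, float] = (100.0, 0.0)  # (positive, negative)
    control_sd: float = 1.0
    hit_relation: Callable[[float], float] = lambda y: y
    n_control_wells: int = 16
    noise_sd: float = 0.0
    seed: int = 0


def synth_inventory(
    counts: dict[ReagentClass, int], seed: int = 0
) -> Inventory:
    """Generate a plausible inventory: unique names, valid SMILES, MW 80-600.

    Deterministic in the seed; reagent names are "<Class>-<k>".
    """
    rng = np.random.default_rng(seed)
    reagents: list[Reagent] = []
    i = 0
    for cls in sorted(counts, key=lambda c: c.value):
        n = counts[cls]
        if n < 0:
            raise ValueError(f"negative count for {cls.value}")
        for k in range(1, n + 1):
            smiles = _SMILES_POOL[i % len(_SMILES_POOL)]
            i += 1
            reagents.append(
                Reagent(
                    name=f"{cls.slug}-{k:02d}",
                    molecular_weight=round(float(rng.uniform(80.0, 600.0)), 2),
                    reagent_class=cls,
                    smiles=smiles,
                    density=round(float(rng.uniform(0.8, 1.6)), 3)
                    if rng.random() < 0.5
                    else None,
                    inventory_location=f"shelf-{rng.integers(1, 9)}",
                )
            )
    if reagents:
        colours = assign_colours(reagents)
        reagents = [
            Reagent(
                name=r.name,
                molecular_weight=r.molecular_weight,
                reagent_class=r.reagent_class,
                smiles=r.smiles,
                density=r.density,
                cas=r.cas,
                inventory_location=r.inventory_location,
                colour=colours[r],
            )
            for r in reagents
        ]
    return Inventory(reagents=reagents, source=f"synthetic(seed={seed})")


def synth_results(
    design: PlateDesign, truth: TruthModel
) -> list[ResultRecord]:
    """Simulate per-well analytics from the planted truth model.

    yield% = base + sum of the well's reagent effects + Normal(0, noise_sd),
    floored at 0. Emitted channels: area_is (constant reference),
    area_product = yield/100 x area_is, and the derived ratio — so a
    calibration with reference_ratio 1.0 recovers the yield exactly.
    """
    rng = np.random.default_rng(truth.seed)
    records: list[ResultRecord] = []
    for well in design.occupied_wells():
        spec = design.reactions[well]
        y = truth.base_yield
        for dose in spec.doses:
            y += truth.effects.get(
                (dose.reagent.reagent_class, dose.reagent.name), 0.0
            )
        y += float(rng.normal(0.0, truth.noise_sd)) if truth.noise_sd > 0 else 0.0
        y = max(y, 0.0)
        area_is = REFERENCE_AREA
        area_product = y / 100.0 * area_is
        records.append(
            ResultRecord(
                well=well,
                channels={
                    "area_product": area_product,
                    "area_is": area_is,
                    "ratio": area_product / area_is,
                },
            )
        )
    return records


def synth_bioassay(
    records: Sequence[ResultRecord],
    spec: AssaySimSpec,
    yield_channel: str = "ratio",
) -> tuple[list[ResultRecord], AssayControls]:
    """Derive inhibition read-outs and control wells from chemistry results.

    inhibition% = hit_relation(yield%) + Normal(0, noise_sd); the yield is
    taken as 100 x the ratio channel. Control signals draw from the stated
    positive/negative distributions. Deterministic in the seed.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[ResultRecord] = []
    for rec in records:
        ratio = rec.get(yield_channel)
        if ratio is None:
            raise ValueError(
                f"well {rec.well.label}: missing channel {yield_channel!r}"
            )
        y = 100.0 * ratio
        inhibition = spec.hit_relation(y)
        if spec.noise_sd > 0:
            inhibition += float(rng.normal(0.0, spec.noise_sd))
        channels = dict(rec.channels)
        channels["inhibition_pct"] = inhibition
        out.append(ResultRecord(well=rec.well, channels=channels))
    mu_p, mu_n = spec.control_means
    if spec.control_sd > 0:
        positive = rng.normal(mu_p, spec.control_sd, spec.n_control_wells)
        negative = rng.normal(mu_n, spec.control_sd, spec.n_control_wells)
    else:
        positive = np.full(spec.n_control_wells, mu_p)
        negative = np.full(spec.n_control_wells, mu_n)
    controls = AssayControls(
        positive=[float(v) for v in positive],
        negative=[float(v) for v in negative],
    )
    return out, controls
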