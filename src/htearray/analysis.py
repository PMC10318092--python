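"""Well-keyed result ingestion and screening analytics.

Covers the chemistry read-out (product/internal-standard peak-area ratios,
calibrated assay yields, regioisomer selectivity) and the direct-to-biology
read-out (percent inhibition against plate controls, the Z' assay-quality
factor, replicate agreement, and four-parameter-logistic IC50 fits).

Missing channel values are propagated as missing: they are excluded from
means and agreement counts, never treated as zero.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core_model import (
    HteArrayError,
    PlateDesign,
    PlateFormat,
    Reagent,
    ReagentClass,
    WellAddress,
    parse_well_label,
)


class AnalysisError(HteArrayError):
    """A result file or analytic computation is invalid."""


class FitError(AnalysisError):
    """A curve fit failed to converge or the data are degenerate."""


@dataclass
class ResultRecord:
    """Named numeric output channels for one well (areas, ratios, yields...)."""

    well: WellAddress
    channels: dict[str, float] = field(default_factory=dict)

    def get(self, channel: str) -> Optional[float]:
        v = self.channels.get(channel)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v


@dataclass(frozen=True)
class Calibration:
    """Product/IS area ratio of an authentic product sample at 100% yield.

    Calibrating against an authentic sample corrects for absorptivity
    differences between products, turning a raw ratio into an assay yield.
    """

    product: Reagent
    reference_ratio: float

    def __post_init__(self) -> None:
        if self.reference_ratio <= 0:
            raise AnalysisError("reference_ratio must be > 0")


@dataclass
class AssayControls:
    """Raw signals of the plate's positive and negative control wells.

    Convention: negative = uninhibited enzyme (0% inhibition), positive =
    fully inhibited (100%).
    """

    positive: list[float]
    negative: list[float]

    def __post_init__(self) -> None:
        if len(self.positive) < 2 or len(self.negative) < 2:
            raise AnalysisError("each control set needs >= 2 values")
        if math.isclose(float(np.mean(self.positive)), float(np.mean(self.negative))):
            raise AnalysisError("control means must be distinct")


@dataclass
class DoseResponse:
    """A fitted four-parameter logistic concentration-response curve."""

    concentrations: list[float]  # uM
    responses: list[float]  # %
    bottom: float
    top: float
    ic50: float  # uM
    hill: float
    residual_norm: float


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------


def read_results(
    path: str | os.PathLike[str], fmt: PlateFormat
) -> list[ResultRecord]:
    """Read a well-keyed CSV of numeric channels.

    The file must have a ``well`` column of plate labels; every remaining
    header is a channel. Duplicate wells and non-numeric cells raise;
    empty cells are recorded as missing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "well" not in df.columns:
        raise AnalysisError(f"{path}: missing 'well' column")
    channels = [c for c in df.columns if c != "well"]
    if not channels:
        raise AnalysisError(f"{path}: no channel columns")
    records: list[ResultRecord] = []
    seen: set[WellAddress] = set()
    for i, row in df.iterrows():
        well = parse_well_label(row["well"], fmt)
        if well in seen:
            raise AnalysisError(f"{path}: duplicate well {row['well']}")
        seen.add(well)
        values: dict[str, float] = {}
        for ch in channels:
            cell = row[ch].strip()
            if cell == "":
                continue  # missing, not zero
            try:
                values[ch] = float(cell)
            except ValueError:
                raise AnalysisError(
                    f"{path}: non-numeric value {cell!r} in channel {ch!r}, "
                    f"well {row['well']}"
                ) from None
        records.append(ResultRecord(well=well, channels=values))
    return records


# ---------------------------------------------------------------------------
# Chemistry analytics
# ---------------------------------------------------------------------------


def product_is_ratio(area_product: float, area_is: float) -> float:
    """UV peak-area ratio of product over internal standard."""
    if area_is <= 0:
        raise AnalysisError("internal-standard area must be > 0")
    return area_product / area_is


def assay_yield(ratio: float, cal: Calibration) -> float:
    """Calibrated yield in percent: 100 x ratio / reference_ratio.

    Values above 100% are returned as-is (evidence of calibration or
    integration error), never clipped; callers may flag them.
    """
    return 100.0 * ratio / cal.reference_ratio


def selectivity(areas: Mapping[str, float]) -> dict[str, float]:
    """Fraction of total signal per product (e.g. regioisomer distribution)."""
    total = sum(areas.values())
    if total <= 0:
        raise AnalysisError("all product areas are zero")
    return {name: a / total for name, a in areas.items()}


# ---------------------------------------------------------------------------
# Bioassay analytics
# ---------------------------------------------------------------------------


def percent_inhibition(signal: float, controls: AssayControls) -> float:
    """Normalize a raw signal to percent inhibition against plate controls.

    100 x (mean_negative - signal) / (mean_negative - mean_positive); the
    negative control (uninhibited) maps to 0%, the positive (fully
    inhibited) to 100%.
    """
    mu_n = float(np.mean(controls.negative))
    mu_p = float(np.mean(controls.positive))
    return 100.0 * (mu_n - signal) / (mu_n - mu_p)


def z_prime(controls: AssayControls) -> float:
    """Assay-quality statistic Z' = 1 - 3(sd_p + sd_n) / |mean_p - mean_n|.

    Uses sample (n-1) standard deviations. Z' near 1 indicates wide
    separation between the control bands; Z' <= 0 means they overlap.
    """
    mu_p = float(np.mean(controls.positive))
    mu_n = float(np.mean(controls.negative))
    sd_p = float(np.std(controls.positive, ddof=1))
    sd_n = float(np.std(controls.negative, ddof=1))
    return 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)


def replicate_agreement(
    pairs: Sequence[tuple[float, float]],
    threshold: float = 0.10,
    eps: float = 1e-12,
) -> float:
    """Fraction of replicate pairs agreeing within a relative-error threshold.

    A pair agrees when |a - b| / max(|a|, |b|, eps) < threshold; pairs where
    both values are zero agree by the eps guard.
    """
    if not pairs:
        raise AnalysisError("replicate_agreement requires at least one pair")
    ok = 0
    for a, b in pairs:
        if abs(a - b) / max(abs(a), abs(b), eps) < threshold:
            ok += 1
    return ok / len(pairs)


def four_pl(x: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    """y = bottom + (top - bottom) / (1 + (x / ic50)^hill)."""
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def fit_dose_response(
    concentrations: Sequence[float],
    responses: Sequence[float],
    max_iter: int = 2000,
) -> DoseResponse:
    """Least-squares 4PL fit of a concentration-response curve.

    The fit works on log-concentration internally (ic50 is optimized as its
    logarithm, guaranteeing ic50 > 0) with a deterministic initialization:
    bottom = min(y), top = max(y), ic50 = concentration nearest the
    half-maximal response, hill = 1. Flat or non-convergent data raise
    :class:`FitError` rather than returning a spurious fit.
    """
    order = np.argsort(np.asarray(concentrations, dtype=float), kind="stable")
    x = np.asarray(concentrations, dtype=float)[order]
    y = np.asarray(responses, dtype=float)[order]
    if len(x) < 4:
        raise FitError("need >= 4 concentration-response points")
    if len(set(x.tolist())) < 3:
        raise FitError("need >= 3 distinct concentrations")
    if np.any(x <= 0):
        raise FitError("concentrations must be > 0")
    span = float(np.max(y) - np.min(y))
    if span < 1e-9 * max(1.0, float(np.max(np.abs(y)))):
        raise FitError("responses are flat; no dose-response to fit")

    bottom0, top0 = float(np.min(y)), float(np.max(y))
    half = (bottom0 + top0) / 2.0
    ic50_0 = float(x[int(np.argmin(np.abs(y - half)))])

    def resid(p: np.ndarray) -> np.ndarray:
        bottom, top, log_ic50, hill = p
        return four_pl(x, bottom, top, math.exp(log_ic50), hill) - y

    res = least_squares(
        resid,
        x0=np.array([bottom0, top0, math.log(ic50_0), 1.0]),
        method="lm",
        max_nfev=max_iter,
    )
    if not res.success:
        raise FitError(f"4PL fit did not converge: {res.message}")
    bottom, top, log_ic50, hill = res.x
    return DoseResponse(
        concentrations=[float(v) for v in x],
        responses=[float(v) for v in y],
        bottom=float(bottom),
        top=float(top),
        ic50=float(math.exp(log_ic50)),
        hill=float(hill),
        residual_norm=float(np.linalg.norm(res.fun)),
    )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


def top_performers(
    design: PlateDesign,
    records: Sequence[ResultRecord],
    channel: str,
) -> dict[ReagentClass, list[tuple[str, float]]]:
    """Rank each class's reagents by mean channel value over their wells.

    Returns, per reagent class present in the design, (reagent name, mean)
    pairs sorted best-first; ties break alphabetically by name. Wells with
    a missing channel value are excluded from the means.
    """
    by_well = {r.well: r for r in records}
    for r in records:
        if r.well not in design.reactions:
            raise AnalysisError(f"result for unoccupied well {r.well.label}")
    if not any(r.get(channel) is not None for r in records):
        raise AnalysisError(f"channel {channel!r} absent from the results")

    sums: dict[ReagentClass, dict[str, list[float]]] = {}
    for well in design.occupied_wells():
        rec = by_well.get(well)
        if rec is None:
            continue
        value = rec.get(channel)
        if value is None:
            continue
        for dose in design.reactions[well].doses:
            cls = dose.reagent.reagent_class
            sums.setdefault(cls, {}).setdefault(dose.reagent.name, []).append(value)
    ranking: dict[ReagentClass, list[tuple[str, float]]] = {}
    for cls, per_reagent in sums.items():
        means = [(name, float(np.mean(vals))) for name, vals in per_reagent.items()]
        means.sort(key=lambda t: (-t[1], t[0]))
        ranking[cls] = means
    return ranking
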