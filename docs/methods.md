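# Methods

`htearray` models the computational side of a high-throughput-experimentation
(HTE) campaign: turning a chemical inventory into a multiplexed reaction
array on a standard wellplate, deriving the bench work (stock solutions and
transfers) that realizes it, mapping a 1536-well reaction plate onto its
384-well analytical daughters, and reducing well-keyed analytical or
bioassay read-outs to the statistics chemists act on. This note records the
model, the defaults, and the choices made where more than one reasonable
design existed.

## Plate model

Plates are rectangular grids: 24 = 4x6, 96 = 8x12, 384 = 16x24,
1536 = 32x48. Internally all addressing is 0-based (row, col); printed
labels use letter rows and 1-based columns ("B3"). Rows beyond Z continue
AA, AB, ... AF, so the last 1536-plate well is AF48. Row-major order is the
canonical iteration and serialization order everywhere — designs, transfer
lists, and output files all read like the plate does.

## Factorial layout

An experiment's factors are reagent groups keyed by role class
(Electrophile, Nucleophile, Catalyst1, Catalyst2, Ligand1, Ligand2,
Base/Acid, Reductant/Oxidant, Solvent1, Additive, Other — a closed set of
eleven). The design is the full Cartesian product of the groups, times an
optional replicate count; it fits a plate iff that product is at most the
well count. Size-one groups are "global": they appear in every reaction and
consume no axis.

The automatic axis assignment is deterministic. Varying classes are ordered
by a fixed priority (Ligand1, Catalyst1, Catalyst2, Ligand2, Additive,
Base/Acid, Reductant/Oxidant, Electrophile, Nucleophile, Other; ties by
input order) and assigned greedily to the row axis while the running
product fits within the row count; the rest go to columns, replicates
occupying adjacent columns. If the column product overflows, the
lowest-priority column classes are pushed back to the rows while they fit.
This reproduces the two canonical groupings: 4 ligands x (3 catalysts x 2
additives) lands as 4 rows x 6 columns on a 24-well plate, and 12 ligands x
8 catalysts puts one catalyst per row and one ligand per column on a
96-well plate. Factor sets with no exact packing (e.g. 80 x 8 x 2 on a
1536 plate) fall back to a row-major sequential fill of the combination
list, replicate copies adjacent — the layout is then still complete and
deterministic, just not axis-aligned.

`replicate_expand` re-packs a design so each reaction's n copies occupy
consecutive row-major wells. Re-packing (rather than inserting copies next
to originals in place) is the only convention that is well-defined for
designs with arbitrary gaps; n = 1 returns the design unchanged.

## Stoichiometry

Loadings are dimensionless equivalents relative to the limiting reagent
(mol% stored as fractional equivalents: 20 mol% = 0.20). The limiting
reagent is the dose tagged as such, or else the first dose at 1.0 equiv in
class-priority order. Per-well amount = scale (mmol) x loading; aliquot
volume = 1000 x mmol / molarity (uL); stock mass = molarity x prepared
volume x MW x 1e-3 (mg).

Defaults, all overridable per factor set:

| parameter | default | rationale |
|---|---|---|
| scale | 0.01 mmol | typical microscale HTE well |
| reaction volume | 100 uL | fits every supported plate |
| stock molarity | 0.5 M substrates / 0.1 M catalytic classes | keeps aliquots in the 2–20 uL band |
| loading | 1.0 equiv substrates / 0.20 equiv catalytic classes | 20 mol% is the common screening loading |
| dead volume | 20% | pipetting loss allowance |
| minimum transfer | 0.5 uL | mosquito-class dispenser floor |

One stock is prepared per (reagent, molarity, solvent) triple; a neat
solvent source per solvent supplies the top-up that brings each well to its
reaction volume. Neat sources carry no concentration or mass bookkeeping,
so the mass–molarity consistency invariant applies to dissolved stocks
only. An aliquot below the minimum transfer raises an error (the remedy is
a more dilute stock); solvent top-ups below 0.01 uL are dropped as
round-off. Suspensions (e.g. an inorganic base in DMSO) are flagged in the
bench instructions but computed identically to solutions.

## 1536 -> 4 x 384 splitting

The quadrant convention is interleaved stamping: parent well (r, c) maps to
daughter 2·(r mod 2) + (c mod 2) + 1 at (r div 2, c div 2). This is the
standard convention for parity-interleaving liquid handlers; the mapping is
isolated behind `quadrant_of`/`parent_of`, so a block convention would be a
local swap. Each 384-well daughter reserves whole control columns
(default 1, 2, 23, 24 — the outermost pairs, roles alternating
positive/negative); the corresponding parent wells (|columns| x 16 rows x 4
daughters) are excluded from layout, so a full 80 x 8 x 2 campaign places
exactly 1280 reactions and leaves 256 parent wells free — four control
columns per daughter. Daughter designs carry each well's parent label in
metadata so results re-join unambiguously.

## Analytics

* **Ratio and yield.** The product/internal-standard UV peak-area ratio
  normalizes detector response; dividing by the ratio of an authentic
  product sample (equimolar IS, 100% yield) converts it to an assay yield
  in percent. Yields above 100% are reported as-is — they are evidence of a
  calibration or integration problem and clipping would hide it.
* **Selectivity** is the fraction of summed signal per product; fractions
  sum to one by construction.
* **Inhibition** is normalized linearly between the plate's control means:
  negative control (uninhibited enzyme) = 0%, positive (fully inhibited)
  = 100%.
* **Z'** = 1 − 3(σp + σn)/|μp − μn| with sample (n−1) standard deviations,
  the usual screening-assay quality statistic.
* **Replicate agreement** is the fraction of pairs with relative error
  |a−b|/max(|a|,|b|,ε) under a threshold (default 10%); the ε guard makes
  both-zero pairs count as agreeing.
* **Dose–response** is a least-squares four-parameter logistic
  y = bottom + (top − bottom)/(1 + (x/IC50)^hill), optimized over
  log(IC50) so the estimate stays positive, initialized deterministically
  from the data (bottom = min y, top = max y, IC50 = concentration nearest
  half-maximum, hill = 1). Flat responses raise rather than fit.
* **Missing data** (empty result cells) stay missing: excluded from means,
  rankings and agreement counts, never coerced to zero.
* **Top performers** ranks each class's reagents by the mean of a chosen
  channel over the wells containing them; ties break alphabetically.

## Output formats

The experiment record is one CSV row per reaction:
`plate,well`, then `<class>_name,_smiles,_loading,_molarity` per populated
class in priority order (class labels slugified: `base_acid`, ...), then
`solvent,scale_mmol,volume_ul,temperature_c,time_h`, then one column per
result channel. Numeric cells are written with full precision (`repr`) so
the file round-trips exactly. Collation concatenates such files under a
schema union with a provenance column. The JSON export nests
experiment → reactions → inputs/outcomes with stable key order, inputs in
class priority order.

The chemical-space embedding fingerprints unique product SMILES (2048-bit
Morgan, radius 2), runs tSNE (perplexity min(5, n−1), PCA initialization,
caller-supplied seed) and colours each product by the mean of a chosen
channel; products are processed in sorted-SMILES order so row order cannot
permute the output.

## Synthetic data

The generators exist so every stage is testable without laboratory files.
`synth_inventory` draws molecular weights uniformly on 80–600 g/mol and
assigns structures from a fixed pool of valid fragments (so fingerprinting
never fails). `synth_results` uses an additive truth model: yield = base +
Σ planted reagent effects + N(0, σ), floored at 0, emitted as peak areas
with a constant internal standard so the ratio channel recovers the yield.
`synth_bioassay` maps yield through a monotone hit relation to percent
inhibition and draws control wells from stated Normal distributions. Every
generator takes an explicit seed and owns its RNG; no global state.

What this does **not** emulate: correlated well effects (edge evaporation,
dispensing drift), non-additive chemistry (reagent interactions), heavy-
tailed analytical noise, or plate-position artefacts. Tests passing on
these fixtures therefore demonstrate the correctness of the bookkeeping
and statistics, not robustness to real assay pathology.

## Problem sizes and determinism

The test suite and the acceptance script run the campaign-scale layouts at
their natural sizes (1536-well, 1280 reactions) because layout is cheap;
stochastic properties (dosing conservation, top-performer recovery) use
1000 random plans / 100 seeds, which completes in seconds. All randomness
flows from explicit seeds; two runs with the same seed are byte-identical.

## Known limitations

* Only the four rectangular SBS formats; no custom geometries or vial racks.
* One solvent per reaction; varying-solvent factor sets are rejected.
* The axis-assignment heuristic prefers rows for high-priority classes;
  factor sets with many co-prime group sizes fall back to sequential fill
  rather than searching all packings.
* The JSON export is a generic nested record, not a schema-validated
  exchange format.
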