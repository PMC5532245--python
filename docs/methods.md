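# Methods

## Accounting model

### Extent accounts

Land cover is the top-level reporting unit: soil extent is classified by the
14-class SEEA interim land-cover nomenclature rather than by soil taxonomy,
because land-use policy acts on covers, not soil types. CORINE-coded grids
(44 three-digit classes) are aggregated to the 14 SEEA classes with a total
one-to-one mapping that ships as a packaged CSV (`fixtures/corine_to_seea.csv`);
no CORINE class maps to Mangrove, which is why European accounts carry that
class as explicitly absent (serialized `NA`, never 0).

Given two co-registered categorical grids, the change matrix
`F[i][j]` tallies the area that moved from class `i` to class `j`. Its row
and column marginals are the per-class areas at the two epochs, and the
grand total is conserved whenever the classified territory is constant.
A minimum-mapping-unit filter can fold small change patches back into the
diagonal: patches are 4-connected components of the changed-cell mask (any
source/destination pair), and a patch strictly smaller than the threshold is
treated as unchanged. This mirrors how operational change layers are
pre-filtered (typically at 5 ha); the default here is 0 (no filtering)
because synthetic grids are not pre-filtered.

The account itself comes in two modes. **Net** mode (default, the layout of
published SEEA tables) books only the per-class net flow — column sum minus
row sum — as expansion if positive, regression if negative, so at most one of
additions/reductions is nonzero per class. **Gross** mode books total inflow
and outflow separately, because netting can hide large compensating flows
(e.g. forest-to-transitional-scrub transitions within an aggregated class).
Flows of managed classes (default {1, 2, 3, 4}: artificial surfaces and the
cropped systems) go under the managed lines, all others under natural;
woodland is deliberately not split because it is partly managed and partly
not. Reappraisal lines exist in the layout and are always 0 here.

Areas are carried as floating-point km² throughout; integer km² (rounded
half-away-from-zero, the ledger convention) appear only in written reports.
Grids must share shape, cell size, and nodata mask — a cell classified in one
epoch but nodata in the other is an error, not a flow. No reprojection or
resampling is attempted.

### Mass accounts

The soil mass balance per cover class over an accounting step is

    closing_change = formation − eroded_lost ,

where formation = area × rate with a low/high rate pair (default
0.4–1.4 t ha⁻¹, the plausible range for temperate soil production; the upper
bound is consistent with cosmogenic-nuclide estimates of ~0.15 mm yr⁻¹
production, which at a back-solved bulk density of ~1.067 t m⁻³ equals
~1.6 t ha⁻¹ yr⁻¹ — the converter `depth_rate_to_mass_rate` makes the unit
identity explicit: 1 mm over 1 ha = 10 m³). Gross rill+sheet erosion uses
per-class rates (t ha⁻¹) that are *inputs* — typically from a RUSLE-type
model — and is split by a delivery fraction into mass lost to watercourses
and mass redeposited on land. Redeposited mass reappears as a deposition
addition, so within-land redistribution cancels exactly and only the lost
share affects the closing balance.

The delivery fraction defaults to 0.10. It is an empirical workbook constant
of the reference account this package reproduces (every class there has
lost/gross = 0.100 to printed precision), not a process estimate — real
sediment delivery ratios vary strongly with catchment area (field studies
span 98 % down to 2 % from ~1.5 ha to ~300 km²) — and it is overridable per
run. Eight classes carry mass flows (2, 3, 4, 5, 6, 8, 10, 11); artificial
surfaces, mangrove, aquatic vegetation, snow/ice and water bodies are emitted
with empty flows to preserve the 14-column layout. Opening stocks and the
extraction/sealing line are represented as explicitly unknown and serialize
as empty cells.

Rounding: all flows are computed in full precision; at report time the lost
mass is rounded half-away-from-zero first and redeposited takes the remainder
of the rounded gross mass, so the pair always sums exactly. Totals are sums
of rounded components, which makes the conservation identity
`additions − reductions = formation_high − lost` exact in integer tonnes;
closing rows round from the full-precision balance.

The `years` multiplier defaults to 1: the reference table is headed by a
12-year period but its cells equal rate × area × 1, an annual-versus-period
ambiguity this package documents rather than resolves. The packaged per-class
areas (`fixtures/mass_inputs_eu25.csv`) are implied by that table's formation
cells (mass ÷ 1.4) and its gross rates by eroded mass ÷ area; they do not
match the extent-account areas for the same classes (a discrepancy the source
material leaves unexplained), so areas are always an explicit input.

### Condition classification and cross-tabs

SOC classes partition every sample: the map-derived peat flag takes
precedence (peat is defined by a peat-probability map thresholded at > 35 %,
strictly — a mapped property, not a concentration), then organo-mineral
(> 12 % SOC), humus-mineral (3–12 %), mineral (< 3 %). SOC is g/kg at the
interface (survey convention); thresholds convert as 12 % = 120 g/kg,
3 % = 30 g/kg. Boundary conventions, fixed once and tested: "> 12 %" and
"< 3 %" are strict, so both 30 and 120 g/kg are humus-mineral. pH bins are
lower-inclusive with breakpoints 4.5, 5, 6, 7, 8.3, except that 8.3 itself
stays in "7–8.3" because "> 8.3" is strict. The end bins carry physical
meaning (aluminium toxicity below 4.5; boron toxicity/sodicity above 8.3);
the interior divisions are visualisation conventions.

State cross-tabs use a design-based proportional estimator: the area of cover
`c` in condition class `k` is `area_c × n_{c,k} / n_c`. Row sums therefore
equal the cover areas exactly. This is this package's choice of estimator —
how the original survey-based hectare totals were weighted is not specified
in the source material. Change cross-tabs attribute each changed cell to its
nearest sample in grid coordinates (Euclidean; ties break to the lowest
sample id, realised by sorting samples by id before the argmin), a deliberate
simplification of full design-based survey statistics. Since the basis cover
of a changed cell is ambiguous (origin vs destination), the table keys on the
(from, to) pair so both marginals can be formed.

## Synthetic data

The generator emulates the *structure* of the real inputs, not their
marginals:

- **Grids**: an initial mixture over classes is realised either as iid
  per-cell draws (patchiness ≤ 1) or as Voronoi growth from ~`ncells/d²`
  random nuclei for expected patch diameter `d` cells. Epochs advance by
  redrawing each cell independently from its row of a 14×14 Markov transition
  matrix. The 3-binomial-SE guarantee on class shares is exact for iid grids
  and approximate (nuclei-level) for patchy ones.
- **Samples**: cells are sampled uniformly without replacement; SOC is
  lognormal (non-negative, right-skewed, as topsoil carbon is), pH truncated
  normal on (3, 10), peat Bernoulli, all with per-cover parameters. Defaults
  are calibrated qualitatively: tree-covered and aquatic soils carbon-rich,
  cropped and barren soils carbon-poor; crops near-neutral pH, grassland
  moderately acid, woodland acidic, barren/coastal alkaline.
- **Peat surface**: Gaussian-filtered white noise rescaled to [0, 1].

What passing tests show: the tallies, account identities, classifiers and
estimators are correct, and parameters of a known generating process are
recovered within sampling error. What they do not show: agreement with real
survey hectare totals, spatially correlated soil properties (draws are
independent given cover), real land-cover patch geometry, or erosion-rate
realism — per-class rates are always inputs.

The packaged "eu25" scenario is a toy-scale territory dominated by
herbaceous crops and tree cover with a small artificial class growing at the
crops' expense — the qualitative situation of the EU-25 reference account.

## Numerical and design choices

- Rounding is half-away-from-zero everywhere a report prints integers;
  internal computation never rounds.
- The change matrix is a dense 14×14 pandas DataFrame indexed by SEEA codes;
  grids up to a few 10⁷ cells tally in one `bincount` pass.
- Acceptance and recovery checks run at deliberately modest problem sizes
  (200×200 grids, 5,000 samples, 500 oracle trials) — large enough for
  3-SE bounds to be meaningful, small enough to run in seconds.
- `build_extent_account` accepts independent opening areas and validates them
  against the matrix row sums to a configurable absolute tolerance, raising
  with per-class residuals on mismatch.
- Published-style inputs (opening + net flows without a full matrix) enter
  through `extent_account_from_net_changes`; the packaged EU-25 fixture keeps
  the printed values verbatim, including its own ±1 km²/±1 t internal
  rounding inconsistencies, and tests assert only internally consistent cells.

## Known limitations

- No carbon-stock (t C) computation: bulk density is not part of the sample
  record, so only concentration classes are supported.
- No nutrient, contamination, sealing or biodiversity accounts; no monetary
  valuation.
- No map projections, vector inputs, resampling, or catchment routing; the
  delivery fraction is a scalar, not an SDR-area relation.
- The per-cover sample distributions ignore spatial autocorrelation of soil
  properties.
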