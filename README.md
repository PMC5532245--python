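# soilcap

SEEA-style natural-capital accounting for soil, organised by land cover.

National statistical offices and environmental agencies increasingly report
environmental assets through the UN System of Environmental-Economic
Accounting (SEEA). Soil is one of its least developed asset classes: there is
no agreed way to tabulate how much soil a territory has, where it is forming
or eroding away, and in what condition it is, in a form that connects to
economic activity. `soilcap` implements a practical answer for gridded
land-cover data (CORINE-style) and point topsoil surveys (LUCAS-style):

1. **Extent accounts** — land area per SEEA land-cover class, with additions
   (expansion) and reductions (regression) between epochs, split into managed
   flows (artificial surfaces and cropped systems) and natural flows. For
   classes `i, j` with epoch-pair area flows `F[i][j]` (km²), the net-mode
   account books `net_j = Σ_i F[i][j] − Σ_k F[j][k]` as expansion when
   positive, regression when negative, and enforces the identity
   `closing = opening + additions + reductions` per class.
2. **Mass accounts** — a per-class soil mass balance in tonnes: formation
   bounded by low/high rates (default 0.4–1.4 t ha⁻¹), gross rill+sheet
   erosion at per-class rates, and a sediment-delivery split of eroded mass
   into redeposition on land (mass-neutral: it reappears as deposition) and
   loss to watercourses (default delivery fraction 0.10). The closing change
   per class reduces to `formation − lost`.
3. **Condition cross-tabs** — topsoil samples classified by organic carbon
   (peat by map; otherwise organo-mineral > 12 % SOC, humus-mineral 3–12 %,
   mineral < 3 %) and by six pH bins (breakpoints 4.5, 5, 6, 7, 8.3), then
   cross-tabulated into hectares per (land cover × condition class) with a
   design-based proportional estimator, and per land-cover *change* with
   nearest-sample attribution.
4. **Synthetic data** — patchy categorical land-cover grids evolving under a
   known per-cell Markov transition matrix, per-cover SOC/pH sample
   distributions, and a smooth peat-probability surface, so the estimators
   can be validated end-to-end by parameter recovery without external data.

## Worked example

```python
import soilcap as sc
from soilcap.reporting import load_extent_inputs

# Extent account from the packaged EU-25 inputs (km²)
opening, net = load_extent_inputs()
acct = sc.extent_account_from_net_changes(opening, net, epoch_pair=("2000", "2012"))
print("artificial surfaces: opening", int(acct.table.at["opening", 1]),
      "expansion", int(acct.table.at["managed_expansion", 1]),
      "closing", int(acct.table.at["closing", 1]))

# Soil mass account from the packaged per-class areas and erosion rates (t)
areas, erosion = sc.load_mass_inputs()
mass = sc.build_mass_account(areas, erosion=erosion)
r = mass.rounded()
print("herbaceous crops closing stock (1.4 t/ha):", int(r.at["closing_high", 2]))
print("terrestrial barren closing stock (1.4 t/ha):", int(r.at["closing_high", 11]))
```

prints

```
artificial surfaces: opening 99128 expansion 8354 closing 107482
herbaceous crops closing stock (1.4 t/ha): 125156728
terrestrial barren closing stock (1.4 t/ha): -81032
```

Artificial surfaces grew by 8,354 km² over 2000–2012 (urban sprawl, booked as
managed expansion) to a closing extent of 107,482 km². Under the optimistic
formation bound, herbaceous cropland still accumulates soil mass
(+125.2 Mt net change), while terrestrial barren land loses mass even at the
upper formation bound (−81,032 t): erosion there outpaces any plausible
formation, so the class is flagged as depleting by
`sc.net_balance_summary(mass)` (as is sparsely vegetated land).

The same pipeline runs from the shell:

```sh
soilcap simulate --out sim --seed 7          # synthetic epochs + samples
soilcap extent   --config extent.yaml --out ext
soilcap mass     --out massacct
soilcap condition --config cond.yaml --out cond
```

Every command echoes its configuration into the output directory and writes a
`manifest.json` of output checksums; identical config + seed gives
byte-identical outputs.

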