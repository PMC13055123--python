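# Methods

This note documents the model behind `lacticycle`: its balances, the
calibrated constants, the conventions chosen where the design was genuinely
open, and what the synthetic scenarios do and do not emulate.

## Scope and assumptions

The model is a steady-state, reaction-free material balance around a five-step
recovery train integrated into a 10,000 MTA cultivated-meat (CM) facility.
All aqueous streams up to the evaporator feed are treated as dilute with a
density of 1.00 kg/L, so volumetric rates equal total mass rates; the 88 wt%
product is tracked by mass only. Cations are carried as charge equivalents
(eq/h) with negligible mass, because the ion-exchange step is sized on
equivalents, not salt mass. Ammonia is carried in the composition book but has
no downstream effect (no unit operation acts on it). There is no membrane
transport model, breakthrough dynamics, pH speciation, or heat-exchanger
network — sieving fractions, working capacities and steam economies are the
modeling primitives, as is usual for conceptual TEA.

## Flowsheet balances

* **Spent media rate**: `Q = media_per_batch / batch_mass × annual CM / hours`
  = 58,597 L/h at the defaults.
* **MF (15×)**: retentate volume `Q/15` (~3,900 L/h); protein fully retained;
  all other solutes distribute uniformly in the water phase, so the passage
  fraction is `(CF−1)/CF`. `mf_la_passage` can override the lactate split.
* **AC**: glucose removed to a configurable residual (default 0); lactate
  recovery 0.92. One bed holds a 24-h loading cycle's glucose at the working
  capacity; the twin regenerates with 5 bed volumes of recycled water.
  Annualized regenerant water and carbon replacement are independent of the
  cycle length (bed size and cycle count cancel).
* **IEX**: bed volume = cycle equivalents / (2 eq/L); regeneration takes
  3 bed volumes of 1 M H₂SO₄ (0.098 kg/mol); lactate recovery 0.87; salts
  removed completely by default.
* **NF/RO**: lactate yield `retention^stages = 0.95³ = 0.857`; retentate
  volume set so that the retentate concentration is 77 g/L (or, when
  `nf_retentate_volume_lph` is pinned, a fixed volumetric duty — see
  *Sensitivity conventions*). Remaining neutral solutes leave with the
  permeate.
* **MEE**: product mass = lactate / 0.88; evaporated water = feed water −
  product water; steam = evaporated / 4.5. At the baseline this gives
  127.9 kg/h of product (1,024 MT/yr, 64.0% overall recovery) and
  2,372 MT/yr of low-pressure steam.

Overall recovery factorizes exactly into the per-step recoveries
(`14/15 × 0.92 × 0.87 × 0.857375 = 0.6405`). The AC/IEX split (0.92/0.87) is
a modeling choice: only their 0.80 product is pinned by the end-to-end
recovery, and both are ordinary config fields.

## Water balance

The host facility draws `facility_water_per_media` (1.0739) L of water per L
of media and, without recovery, reuses 75% of it. With recovery, NF permeate
(flow K) and MEE distillate (flow L) replace that reuse while the AC beds
consume regeneration water (flow D); flows B, E and H go to treatment. At the
defaults the block is a small net water consumer (~3 L/min, ~1,460 m³/yr) and
avoids ~37 L/min (~17,750 m³/yr) of wastewater. Water closure over the block
(A + D + G in; B, E, H, K, L, M out) holds to machine precision.

## Calibrated constants

Several regeneration/consumable constants are not published for this process.
They are calibrated **once** so the baseline annual budgets match the
reference cost table at the reference unit prices, then treated as fixed
physical inputs:

| constant | default | pinned by |
|---|---|---|
| exchangeable cation load | 0.02508 eq/L | H₂SO₄ budget (1,613 MT/yr) |
| AC glucose capacity / bulk density | 148 g/kg @ 0.45 kg/L | regen water (net ~3 LPM) |
| AC carbon lifetime | 5.84 yr | carbon replacement (5,469 kg/yr) |
| IEX resin lifetime | 2.29 yr | resin replacement (507 ft³/yr) |
| MF / NF membrane price @ flux | 122.42 $/m² @ 50 LMH; 32.67 $/m² @ 20 LMH | membrane lines |
| CIP caustic | 0.011936 kg/m³ media | caustic line |
| specific electricity (MF/AC/IEX/NF/MEE) | 0.15 / 0.10 / 0.10 / 1.50 / 24.18 kWh/m³ | electricity line (1.095 M kWh/yr) |
| facility water basis | 1.0739 L/L media | net water & wastewater deltas |

Notes on two of these. The exchangeable cation load (0.025 eq/L) is far below
full-strength DMEM/F12 salinity (~0.158 eq/L, computed from the packaged salt
table): spent-media cation levels are reported at µg/L–mg/L and only the
exchanged fraction loads the resin; the acid budget fixes the effective value.
The electricity total consistent with the cost table (~1.1 M kWh/yr) is used
for both costing and the life-cycle inventory; a ~1.4 M kWh/yr figure also in
circulation for this flowsheet is inconsistent with that cost line, and the
specific energies are config fields if a user prefers it. The NF pumps
dominate electricity, followed by the MEE vacuum/cooling systems.

## Economics

* Capital: installed-cost anchors per unit op at frozen baseline capacities,
  scaled by `(capacity / anchor)^0.7` and CEPCI-adjusted (identity at the
  2023 defaults). An exponent of 0.6 would push the COGS response to a −25%
  media-rate change to +5.3%, outside the ≤4% behavior this flowsheet
  exhibits; 0.7 (equally standard for process equipment) gives +3.9%/−2.8%.
* Depreciation: flat 15 years, no salvage, no tax/discounting/working
  capital; buildings, engineering, contingency, startup, utility-plant
  capital and labor are excluded.
* `COGS/kg(88%) = (CAPEX/15 + OPEX) / annual 88% mass` = $0.71/kg.
  Revenue ($1.41/kg) and annual COGS are booked on contained (100%) tonnage —
  the only convention under which the reference revenue/COGS/profit/payback
  set is mutually consistent. Break-even therefore occurs at a contained
  price equal to the per-kg (88% basis) COGS.
* The billed net-water (24.5 MT/yr) and wastewater-credit (14,736 m³/yr)
  quantities are pinned in the cost book (scaled with media rate) because the
  reference cost table's water lines are not consistent with any physical
  water balance of this flowsheet; set them to `None` to bill the physical
  flows instead (≈ +$1,450 / −$26,600, a 0.8% OPEX shift). The life-cycle
  inventory always uses the physical flows.

## Life-cycle assessment

Functional unit: 1 kg of 88 wt% lactic acid. Inventory = annual ledger /
annual product mass; equipment manufacture excluded. Impact factors are
configuration, not database lookups: the shipped seed is a set of
literature-plausible per-unit GWP/CED values with steam dominant, and
`calibrate_factors` rescales each impact by a single multiplier so the
baseline totals equal the 3.0 kg CO₂eq / 44 MJ anchors exactly (steam then
contributes 66% of GWP and 56% of CED, satisfying the >50% dominance
property; calibration is idempotent and invariant to uniform seed rescaling).
Factors are calibrated once against the baseline scenario and held fixed for
sweeps — they are properties of the inventory items, not of the scenario.
The effective calibrated steam factor (~0.85 kg CO₂eq/kg steam) is high for
bare natural-gas steam and should be read as carrying co-allocated upstream
burdens implied by the anchors.

Allocation per kg CM with co-product yield `y` (≈0.1024 kg 88% LA/kg CM):
total = baseline + y·(recovery burden); mass allocation divides by `1 + y`;
economic allocation by revenue shares ($20/kg CM vs `y·0.88·$1.41`);
substitution subtracts `y ×` the fermentation reference (4.0 kg CO₂eq,
62 MJ = anchors plus the 1.0 kg CO₂eq / 18 MJ advantage over fermentation).
Using the computed yield rather than a rounded 0.1 reproduces the reference
CED rows (256 / 281 / 276 MJ) as well as the GWP rows (13.2 / 14.4 / 14.1).
Percent-change columns are computed against the unrounded baseline, so they
can differ from tabulations derived from rounded intermediates by a few
tenths of a percent; these are reported, not chased.

## Sensitivity conventions

* **Titer axis (1–5 g/L)**: the installed equipment does not change when the
  feed titer does, so every volumetric duty (MF/AC/IEX throughput, NF
  permeate removal, regeneration schedules, pump electricity) stays at its
  baseline level: the sweep pins `nf_retentate_volume_lph` to the baseline
  value. The retentate titer and the evaporation duty then move with the
  feed, and per-kg burdens scale slightly *faster* than inverse titer
  (3.13× at 1 g/L), giving 9.4 / 1.72 kg CO₂eq per kg LA at 1 / 5 g/L and a
  $0.42/kg recovery cost at 5 g/L. A fixed-77 g/L rule under the sweep would
  instead hold per-kg steam constant and flatten the response (≈2.6 at
  5 g/L), which does not match how this flowsheet's economics respond;
  standalone `run_nf` keeps the 77 g/L target.
* **Media-rate axis (±25%)**: everything scales volumetrically, so per-kg
  inventories are bit-identical and only the power-law capital charge moves
  COGS (≤4% either way).
* **Monte Carlo**: joint sampling via the synthetic module; percentile
  summaries of COGS/GWP/CED; reproducible for a fixed seed.

## Synthetic scenarios

The sampler emulates the *structure* of spent media and the study's scenario
ranges: uniform lactate 1–5 g/L, glucose 0.9–2.7 g/L, protein 0.25–1 g/L,
media intensity 46.9 × [0.75, 1.25] L/kg, cations uniform in a DMEM/F12-
plausible 0.14–0.18 eq/L band (bracketing the 0.158 eq/L computed from the
packaged `dmem_f12_salts.csv`), triangular ±20% price multipliers, and
log-normal (σ = 0.2) perturbations of the calibrated impact factors. Note the
sampled cation band deliberately spans full-media salinity, so sampled acid
demands are typically several times the calibrated baseline and many samples
are economically non-viable — useful for stress-testing the pipeline's total-
function property, but not a forecast. The sampler does not emulate cell
metabolism, media depletion kinetics, correlations between fields, or
measurement noise; passing property tests therefore demonstrate internal
consistency of the model, not agreement with real facilities.

## Numerical choices and degenerate inputs

Component conservation is enforced to 1e-9 relative at every unit op and the
whole chain equals a closed-form end-to-end balance on random scenarios to the
same tolerance. Zero lactate feed yields a zero product with a `zero_feed`
flag and a recovery reported as 0; zero glucose or cations collapse the
corresponding bed, regenerant and cost lines to zero. The evaporator accepts a
feed exactly at 88 wt% (zero steam) and rejects a richer one. Unknown config
keys warn rather than fail; invalid values raise naming the field. Problem
sizes throughout (single steady-state balance; 100-sample property runs;
≤1,000-sample Monte Carlo in tests) keep the full suite under a few seconds.

## Known limitations

* Conceptual sieving/capacity model; no validation against pilot data.
* The AC/IEX recovery split, the facility water basis, and the effective
  cation load are calibrated, not measured; they are single numbers standing
  in for unpublished process detail.
* Impact factors are calibrated effective values, not an LCI database; only
  totals and the dominant-steam structure are meaningful, not individual
  factor magnitudes.
* Costing excludes labor, indirect capital and disposal; financials are
  simple payback only (no NPV/IRR).
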