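# lacticycle

Techno-economic and life-cycle model of **lactic acid recovery from
cultivated-meat spent media**.

Scaled cultivated-meat (CM) production co-produces enormous volumes of spent
cell-culture media. Its most abundant metabolite, lactic acid (held near
3 g/L to avoid growth inhibition), is today flushed to wastewater treatment.
`lacticycle` models a conceptual five-step separation train that upgrades that
dilute stream to an 88 wt% polymer-grade lactic acid co-product, and asks
whether doing so pays — in dollars, carbon, energy and water — inside a
hypothetical 10,000 MTA CM facility (46.9 L media per kg CM, 8000 h/yr).

The package is aimed at bioprocess/TEA-LCA analysts: every input is a
validated, serializable parameter book, every table is recomputed from those
inputs, and sensitivity/Monte Carlo sweeps rerun the whole pipeline.

## The model

Spent media at rate `Q = (V_batch / m_batch) · P / H` (baseline 58,597 L/h)
passes through five unit operations (flows A–M):

1. **Microfiltration (MF)** — 15× concentration factor; proteins/debris to
   the retentate, solutes travel with the water phase (lactate passage
   `(CF−1)/CF = 14/15`).
2. **Activated carbon (AC)** — duplex beds remove glucose; regeneration takes
   5 bed volumes of recycled water per loading cycle.
3. **Ion exchange (IEX)** — duplex cation beds sized at 2 eq/L resin
   capacity; regenerated with 3 bed volumes of 1 M H₂SO₄.
4. **Nanofiltration/RO (NF)** — three stages at 95% lactate retention each
   (yield `0.95³ = 86%`), dewatering the stream to 77 g/L.
5. **Multi-effect evaporation (MEE)** — five effects at a steam economy of
   4.5 concentrate to the 88 wt% product
   (`steam = evaporated water / 4.5`).

Overall recovery factorizes as
`14/15 × 0.92 (AC) × 0.87 (IEX) × 0.857 (NF) = 64%`.
Component mass is conserved exactly at every step; NF permeate and MEE
distillate are returned to the facility's water balance.

Downstream of the flowsheet:

* **Economics** — installed capital per unit op scales as
  `anchor · (capacity/anchor capacity)^0.7` with CEPCI escalation; operating
  costs price the annual chemical/consumable/utility ledger;
  `COGS = (CAPEX/15 yr + OPEX) / annual product`; revenue and annual COGS are
  booked on contained (100%) lactic acid tonnage.
* **LCA** — inventory per kg of 88% product (steam, electricity, H₂SO₄,
  caustic, carbon, resin, membranes, net water, avoided wastewater);
  GWP/CED via configurable impact factors calibrated to the 3.0 kg CO₂eq /
  44 MJ baseline anchors; co-product allocation by **mass**, **economic
  value** and **substitution** against a fermentation reference
  (4.0 kg CO₂eq, 62 MJ per kg 88% LA).
* **Sensitivity** — titer sweep 1–5 g/L (installed equipment held at its
  baseline volumetric duty), media-rate sweep ±25%, and seeded Monte Carlo
  over the synthetic-scenario sampler.

## Worked example

```python
from lacticycle import baseline_bundle, run_bundle

res = run_bundle(baseline_bundle())
fs, fin = res.flowsheet, res.financial
print(f"feed {fs.media_rate_lph:,.0f} L/h -> product {fs.product_rate_88pct:.1f} kg/h "
      f"({fs.annual_product_mt:,.0f} MT/yr) at {fs.overall_recovery:.0%} recovery")
print(f"CAPEX ${res.capex.total:,.0f}, OPEX ${res.opex.total_annual:,.0f}/yr, "
      f"COGS ${fin.cogs_per_kg_88pct:.2f}/kg")
print(f"profit ${fin.annual_profit/1e6:.2f} MM/yr, payback {fin.simple_payback_years:.1f} yr")
print(f"GWP {res.la_impact.gwp:.1f} kg CO2eq/kg, CED {res.la_impact.ced:.0f} MJ/kg")
print("CM burden:", {m: round(a.cm_gwp, 1) for m, a in res.allocations.items()})
```

prints

```
feed 58,597 L/h -> product 127.9 kg/h (1,024 MT/yr) at 64% recovery
CAPEX $4,668,398, OPEX $412,020/yr, COGS $0.71/kg
profit $0.63 MM/yr, payback 7.4 yr
GWP 3.0 kg CO2eq/kg, CED 44 MJ/kg
CM burden: {'mass': 13.2, 'economic': 14.4, 'substitution': 14.1}
```

i.e. recovering the co-product costs $0.71 per kg of 88% solution (vs a
$1.41/kg contained-LA market price), pays back its capital in ~7.4 years,
shaves ~$0.06/kg off CM production cost, and carries a 25% lower carbon
footprint than virgin fermentation lactic acid. Depending on the allocation
view, the CM footprint moves from its 14.2 kg CO₂eq/kg baseline to
13.2 (mass), 14.4 (economic) or 14.1 (substitution).

The same run is available from the shell:

```bash
lacticycle run --out out/ --round-like-paper
lacticycle sweep --axis la_conc --values 1,2,3,4,5 --out out/titer_sweep.csv
lacticycle sample --n 100 --seed 42 --out out/samples/
```

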