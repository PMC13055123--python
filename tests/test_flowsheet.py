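"""Unit-operation balances, the chained flowsheet, and its conservation laws."""

import pytest

from lacticycle.flowsheet import (
    make_feed,
    run_ac,
    run_iex,
    run_mee,
    run_mf,
    run_nf,
    solve_flowsheet,
    spent_media_rate,
)
from lacticycle.scenario import FacilityScenario, baseline_bundle
from lacticycle.synthetic import ScenarioSampler, sample_scenarios


# ---------------------------------------------------------------------------
# spent media rate
# ---------------------------------------------------------------------------

def test_spent_media_rate_baseline(baseline):
    # 144,382 L / 3080 kg batch at 10,000 MTA over 8000 h -> 58,597 L/h
    assert spent_media_rate(baseline.facility) == pytest.approx(58_597, abs=1)


def test_spent_media_rate_forced_arithmetic():
    fac = FacilityScenario(
        media_per_batch=100.0, batch_mass=1.0, cm_annual_production=1e6, operating_hours=8000
    )
    assert spent_media_rate(fac) == pytest.approx(12_500)


def test_spent_media_rate_zero_media():
    fac = FacilityScenario(media_per_batch=0.0)
    assert spent_media_rate(fac) == 0.0


def test_spent_media_rate_rejects_zero_hours():
    with pytest.raises(Exception, match="operating_hours"):
        FacilityScenario(operating_hours=0.0)


# ---------------------------------------------------------------------------
# microfiltration
# ---------------------------------------------------------------------------

def test_mf_retentate_flow_near_3900_lph(baseline_run):
    retentate = baseline_run.flowsheet.streams["B"]
    assert retentate.volumetric_rate == pytest.approx(3900, rel=0.02)


def test_mf_lactate_passes_with_water_phase(baseline):
    feed = make_feed(1000.0, baseline.spent_media)
    report = run_mf(feed, baseline.process)
    assert report.la_recovery == pytest.approx(14.0 / 15.0)
    perm, ret = report.outlets["permeate"], report.outlets["retentate"]
    # uniform solute loading of the water phase on both sides of the membrane
    assert perm["lactic_acid"] / perm["water"] == pytest.approx(
        ret["lactic_acid"] / ret["water"], rel=1e-9
    )


def test_mf_protein_fully_retained(baseline):
    feed = make_feed(1000.0, baseline.spent_media)
    report = run_mf(feed, baseline.process)
    assert report.outlets["permeate"]["protein"] == 0.0
    assert report.outlets["retentate"]["protein"] == pytest.approx(feed["protein"])


def test_mf_zero_protein_feed_splits_by_volume(baseline, bundle):
    bundle.spent_media.protein_conc = 0.0
    feed = make_feed(1000.0, bundle.spent_media)
    report = run_mf(feed, bundle.process)
    ret = report.outlets["retentate"]
    assert ret.total_mass == pytest.approx(feed.total_mass / 15.0)


def test_mf_rejects_concentration_factor_at_or_below_one(bundle):
    bundle.process.mf_concentration_factor = 1.0
    feed = make_feed(1000.0, bundle.spent_media)
    with pytest.raises(ValueError, match="concentration_factor"):
        run_mf(feed, bundle.process)


# ---------------------------------------------------------------------------
# activated carbon
# ---------------------------------------------------------------------------

def test_ac_regen_effluent_carries_all_removed_glucose(baseline_run):
    report = baseline_run.flowsheet.step_reports[1]
    assert report.name == "activated_carbon"
    assert report.outlets["eluate"]["glucose"] == 0.0
    assert report.outlets["regen_effluent"]["glucose"] == pytest.approx(
        report.inlet["glucose"]
    )


def test_ac_annual_carbon_replacement_matches_reference_budget(baseline_run):
    # $27,345 / ($5/kg) = 5,469 kg/yr
    carbon = baseline_run.flowsheet.annual_ledger["activated_carbon_kg"]
    assert carbon == pytest.approx(5469, rel=0.01)


def test_ac_zero_glucose_gives_zero_duty(bundle):
    bundle.spent_media.glucose_conc = 0.0
    feed = make_feed(1000.0, bundle.spent_media)
    report = run_ac(feed, bundle.process)
    assert report.sizing["bed_mass_kg"] == 0.0
    assert report.utility_demands["regen_water_lph"] == 0.0


def test_ac_rejects_zero_capacity(bundle):
    with pytest.raises(Exception, match="ac_glucose_capacity"):
        bundle.process.ac_glucose_capacity = 0.0


# ---------------------------------------------------------------------------
# ion exchange
# ---------------------------------------------------------------------------

def test_iex_annual_acid_matches_reference_budget(baseline_run):
    # $145,191 / ($90/MT) = 1,613 MT/yr of H2SO4
    acid_mt = baseline_run.flowsheet.annual_ledger["sulfuric_acid_kg"] / 1000.0
    assert acid_mt == pytest.approx(1613, rel=0.01)


def test_iex_zero_cations_means_zero_bed_and_acid(bundle):
    bundle.spent_media.cation_equivalents = 0.0
    feed = make_feed(1000.0, bundle.spent_media)
    report = run_iex(feed, bundle.process)
    assert report.sizing["bed_volume_l"] == 0.0
    assert report.utility_demands["sulfuric_acid_kg_per_h"] == 0.0


def test_iex_acid_demand_is_linear_in_cation_load(bundle):
    feed1 = make_feed(1000.0, bundle.spent_media)
    bundle.spent_media.cation_equivalents *= 2.0
    feed2 = make_feed(1000.0, bundle.spent_media)
    acid1 = run_iex(feed1, bundle.process).utility_demands["sulfuric_acid_kg_per_h"]
    acid2 = run_iex(feed2, bundle.process).utility_demands["sulfuric_acid_kg_per_h"]
    assert acid2 == pytest.approx(2.0 * acid1, rel=1e-12)


# ---------------------------------------------------------------------------
# nanofiltration
# ---------------------------------------------------------------------------

def test_nf_yield_is_retention_to_the_stages(baseline):
    feed = make_feed(1000.0, baseline.spent_media)
    report = run_nf(feed, baseline.process)
    assert report.la_recovery == pytest.approx(0.95**3)
    assert report.la_recovery == pytest.approx(0.857, abs=5e-4)  # "86% yield"


def test_nf_full_retention_keeps_all_lactate(bundle):
    bundle.process.nf_stage_retention = 1.0
    feed = make_feed(1000.0, bundle.spent_media)
    report = run_nf(feed, bundle.process)
    assert report.la_recovery == 1.0
    assert report.outlets["permeate"]["lactic_acid"] == 0.0


@pytest.mark.parametrize("conc", [1.0, 3.0, 5.0])
def test_nf_retentate_always_hits_target_concentration(bundle, conc):
    bundle.spent_media.lactic_acid_conc = conc
    feed = make_feed(1000.0, bundle.spent_media)
    report = run_nf(feed, bundle.process)
    assert report.outlets["retentate"].conc("lactic_acid") == pytest.approx(77.0)


def test_nf_rejects_target_below_feed_concentration(bundle):
    bundle.spent_media.lactic_acid_conc = 80.0
    with pytest.raises(ValueError, match="nf_target_conc"):
        run_nf(make_feed(1000.0, bundle.spent_media), bundle.process)


# ---------------------------------------------------------------------------
# evaporation
# ---------------------------------------------------------------------------

def test_mee_closed_form_balance_per_kg_contained(baseline):
    """At 77 g/L feed (density 1), per kg of contained lactic acid:
    feed 12.99 kg, product 1.136 kg, evaporated 11.85 kg, steam 2.63 kg."""
    from lacticycle.flowsheet import _stream

    feed = _stream("J", {"lactic_acid": 1.0, "water": 1000.0 / 77.0 - 1.0})
    report = run_mee(feed, baseline.process)
    assert feed.total_mass == pytest.approx(12.987, abs=1e-3)
    assert report.outlets["product"].total_mass == pytest.approx(1.1364, abs=1e-4)
    assert report.sizing["evaporation_kg_per_h"] == pytest.approx(11.851, abs=1e-3)
    assert report.utility_demands["steam_kg_per_h"] == pytest.approx(2.634, abs=1e-3)


def test_mee_annual_steam_near_2400_mt(baseline_run):
    steam_mt = baseline_run.flowsheet.annual_ledger["steam_kg"] / 1000.0
    assert steam_mt == pytest.approx(2400, rel=0.05)


def test_mee_feed_at_target_fraction_needs_no_steam(baseline):
    from lacticycle.flowsheet import _stream

    feed = _stream("J", {"lactic_acid": 0.88, "water": 0.12})
    report = run_mee(feed, baseline.process)
    assert report.utility_demands["steam_kg_per_h"] == pytest.approx(0.0, abs=1e-12)


def test_mee_rejects_overconcentrated_feed(baseline):
    from lacticycle.flowsheet import _stream

    feed = _stream("J", {"lactic_acid": 0.95, "water": 0.05})
    with pytest.raises(ValueError, match="target mass fraction"):
        run_mee(feed, baseline.process)


# ---------------------------------------------------------------------------
# chained flowsheet
# ---------------------------------------------------------------------------

def test_baseline_production_rate_and_recovery(baseline_run):
    fs = baseline_run.flowsheet
    assert fs.product_rate_88pct == pytest.approx(127, rel=0.01)
    assert fs.annual_product_mt == pytest.approx(1015, rel=0.01)
    assert fs.overall_recovery == pytest.approx(0.64, abs=0.005)
    assert fs.la_per_kg_cm == pytest.approx(0.1, abs=0.005)


def test_overall_recovery_factorizes_into_step_recoveries(baseline_run):
    fs = baseline_run.flowsheet
    product = 1.0
    for report in fs.step_reports:
        product *= report.la_recovery
    assert fs.overall_recovery == pytest.approx(product, rel=1e-12)


def test_flowsheet_invariant_identities(baseline_run):
    fs = baseline_run.flowsheet
    w = baseline_run.bundle.process.product_mass_fraction
    assert fs.contained_la_rate == pytest.approx(fs.product_rate_88pct * w, rel=1e-12)
    feed_la = fs.media_rate_lph * baseline_run.bundle.spent_media.lactic_acid_conc / 1000.0
    assert fs.overall_recovery == pytest.approx(fs.contained_la_rate / feed_la, rel=1e-12)


def test_zero_lactic_acid_feed_yields_zero_product_with_flag(bundle):
    bundle.spent_media.lactic_acid_conc = 0.0
    result = solve_flowsheet(bundle)
    assert result.product_rate_88pct == 0.0
    assert result.overall_recovery == 0.0
    assert result.zero_feed


def test_component_mass_conserved_at_every_unit_op(baseline_run):
    for report in baseline_run.flowsheet.step_reports:
        assert report.conservation_residual() < 1e-9, report.name


def test_mass_conservation_holds_on_random_scenarios():
    bundles = sample_scenarios(ScenarioSampler(seed=11), 25)
    for b in bundles:
        result = solve_flowsheet(b)
        for report in result.step_reports:
            assert report.conservation_residual() < 1e-9, report.name


def closed_form_product_rate(bundle) -> float:
    """Independent end-to-end balance: one algebraic expression."""
    media, params, facility = bundle.spent_media, bundle.process, bundle.facility
    rate = (
        facility.media_per_batch
        / facility.batch_mass
        * facility.cm_annual_production
        / facility.operating_hours
    )
    cf = params.mf_concentration_factor
    passage = params.mf_la_passage if params.mf_la_passage is not None else (cf - 1) / cf
    contained = (
        rate
        * media.lactic_acid_conc
        / 1000.0
        * passage
        * params.ac_la_recovery
        * params.iex_la_recovery
        * params.nf_stage_retention**params.nf_stages
    )
    return contained / params.product_mass_fraction


def test_modular_chain_equals_closed_form_oracle_on_100_random_scenarios():
    bundles = sample_scenarios(ScenarioSampler(seed=3), 100)
    for b in bundles:
        result = solve_flowsheet(b)
        assert result.product_rate_88pct == pytest.approx(
            closed_form_product_rate(b), rel=1e-9
        )


def test_doubling_media_flow_scales_all_flows_and_preserves_per_kg(bundle):
    base = solve_flowsheet(bundle)
    bundle.facility.cm_annual_production *= 2.0
    doubled = solve_flowsheet(bundle)
    for label, stream in base.streams.items():
        assert doubled.streams[label].volumetric_rate == pytest.approx(
            2.0 * stream.volumetric_rate, rel=1e-9
        )
    for key, value in base.annual_ledger.items():
        per_kg_base = value / base.annual_product_kg
        per_kg_doubled = doubled.annual_ledger[key] / doubled.annual_product_kg
        assert per_kg_doubled == pytest.approx(per_kg_base, rel=1e-9), key
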