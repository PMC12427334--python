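"""Carbon-footprint components against chained hand arithmetic, plus the
linearity structure (additivity, homogeneity) every LCA term must obey."""

import numpy as np
import pytest

from pigcycle.lca import (
    N2O_N_TO_N2O,
    ActivityLedger,
    BreedInventory,
    EmissionFactorSet,
    ManureRecord,
    TransportLeg,
    UnitError,
    cf_energy,
    cf_enteric,
    cf_forage,
    cf_manure,
    cf_transport,
    enteric_factor,
    footprint_from_ledger,
    n2o_from_applied_n,
    sem,
    total_footprint,
)

F = EmissionFactorSet()


def make_ledger(feed_corn_t=10.0, elec_mwh=5.0, n_kg=100.0, head=20, weight=75.0,
                days=150.0, dist=100.0, tonnes=2.0, live_out=2000.0,
                systems=None) -> ActivityLedger:
    return ActivityLedger(
        feed_tonnes_by_breed={"Landrace": {"corn": feed_corn_t}},
        transport_legs=[TransportLeg(distance_km=dist, tonnes=tonnes, vehicle_class="heavy")],
        inventory=[BreedInventory(breed="Landrace", head=head, avg_weight_kg=weight, days=days)],
        energy_use={"electricity": elec_mwh},
        manure=[
            ManureRecord(
                breed="Landrace",
                n_managed_kg=n_kg,
                system_fractions=systems or {"Solid Storage": 1.0},
            )
        ],
        total_live_weight_kg=live_out,
    )


class TestForage:
    def test_corn_aggregate_factor(self):
        ledger = make_ledger(feed_corn_t=1.0)
        assert cf_forage(ledger, F) == pytest.approx(1000 * 0.37)

    def test_zero_feed(self):
        assert cf_forage(make_ledger(feed_corn_t=0.0), F) == 0.0

    def test_unknown_ingredient_rejected(self):
        ledger = make_ledger()
        ledger.feed_tonnes_by_breed["Landrace"]["acorns"] = 1.0
        with pytest.raises(KeyError, match="acorns"):
            cf_forage(ledger, F)

    def test_detailed_mode_requires_parameters(self):
        with pytest.raises(ValueError, match="yield"):
            cf_forage(make_ledger(), F, mode="detailed")

    def test_n2o_chain_from_applied_nitrogen(self):
        # 1 t N -> 0.01 t N2O-N direct -> x 44/28 -> x 298
        direct, indirect = n2o_from_applied_n(1.0, F)
        assert direct == pytest.approx(4.683, abs=0.001)
        assert indirect == pytest.approx(0.05 * 0.003 * N2O_N_TO_N2O * 298)


class TestTransport:
    def test_tonne_km_arithmetic(self):
        ledger = make_ledger(dist=100.0, tonnes=2.0)
        assert cf_transport(ledger, F) == pytest.approx(100 * 2 * 0.321)

    def test_zero_distance(self):
        assert cf_transport(make_ledger(dist=0.0), F) == 0.0

    def test_two_identical_legs_double_one(self):
        one = make_ledger()
        two = make_ledger()
        two.transport_legs = one.transport_legs * 2
        assert cf_transport(two, F) == pytest.approx(2 * cf_transport(one, F))

    def test_unknown_vehicle_class_lists_valid(self):
        bad = make_ledger()
        bad.transport_legs = [TransportLeg(10.0, 1.0, "hovercraft")]
        with pytest.raises(KeyError, match="heavy"):
            cf_transport(bad, F)


class TestEnteric:
    @pytest.mark.parametrize(
        "weight,expected",
        [(75.0, 0.7143), (105.0, 1.0), (76.0, 0.7238)],
        ids=["Landrace-75", "reference-105", "Duroc-76"],
    )
    def test_weight_scaled_factor(self, weight, expected):
        assert enteric_factor(weight, F) == pytest.approx(expected, abs=1e-4)

    def test_linearity_in_weight(self):
        assert enteric_factor(3 * 40.0, F) == pytest.approx(3 * enteric_factor(40.0, F))

    def test_reference_herd_over_full_year(self):
        inv = [BreedInventory("x", 10, 105.0, 365.0)]
        assert cf_enteric(inv, F) == pytest.approx(10 * 1.00 * 28)

    def test_zero_days_and_proration(self):
        assert cf_enteric([BreedInventory("x", 10, 105.0, 0.0)], F) == 0.0
        full = cf_enteric([BreedInventory("x", 10, 105.0, 300.0)], F)
        half = cf_enteric([BreedInventory("x", 10, 105.0, 150.0)], F)
        assert half == pytest.approx(full / 2)


class TestEnergy:
    def test_electricity_mwh(self):
        assert cf_energy(make_ledger(elec_mwh=10.0), F) == pytest.approx(8800.0)

    def test_diesel_tonnes(self):
        ledger = make_ledger(elec_mwh=0.0)
        ledger.energy_use["diesel"] = 1.0
        assert cf_energy(ledger, F) == pytest.approx(3180.0)

    def test_no_energy_is_zero(self):
        assert cf_energy(make_ledger(elec_mwh=0.0), F) == 0.0

    def test_unknown_carrier_rejected(self):
        ledger = make_ledger()
        ledger.energy_use["biogas"] = 1.0
        with pytest.raises(KeyError, match="biogas"):
            cf_energy(ledger, F)


class TestManure:
    def test_anaerobic_digester_direct_n2o_is_zero(self):
        digester = make_ledger(systems={"Anaerobic Digester": 1.0}).manure
        no_direct = make_ledger(systems={"Liquid/Slurry (No Natural Crust)": 1.0}).manure
        # both systems have a zero direct factor, so totals reduce to the
        # identical CH4 + indirect terms
        assert cf_manure(digester, F) == pytest.approx(cf_manure(no_direct, F))

    def test_intensive_composting_direct_term(self):
        manure = [ManureRecord("x", 100.0, {"Composting (Intensive Turned)": 1.0})]
        lo = EmissionFactorSet(
            manure_ch4_factor=0.0, volatilization_rate_manure=0.0, leaching_rate_manure=0.0
        )
        assert cf_manure(manure, lo) == pytest.approx(100 * 0.1 * N2O_N_TO_N2O * 298, rel=1e-6)
        assert 100 * 0.1 * N2O_N_TO_N2O * 298 == pytest.approx(4683, abs=1)

    def test_zero_nitrogen_is_zero(self):
        manure = [ManureRecord("x", 0.0, {"Solid Storage": 1.0})]
        assert cf_manure(manure, F) == 0.0

    def test_unknown_system_rejected(self):
        manure = [ManureRecord("x", 10.0, {"Moon Disposal": 1.0})]
        with pytest.raises(KeyError, match="Solid Storage"):
            cf_manure(manure, F)

    def test_strict_printed_gwp_flag_scales_ch4_term(self):
        manure = [ManureRecord("x", 100.0, {"Anaerobic Digester": 1.0})]
        loose = EmissionFactorSet(volatilization_rate_manure=0.0, leaching_rate_manure=0.0)
        strict = EmissionFactorSet(
            volatilization_rate_manure=0.0, leaching_rate_manure=0.0,
            strict_printed_manure_gwp=True,
        )
        assert cf_manure(manure, strict) == pytest.approx(cf_manure(manure, loose) * 298 / 28)


class TestTotalFootprint:
    def test_per_kg_components_sum(self):
        bd = total_footprint(4.15, 0.0, 2.65, 0.0, 1.50, live_weight=1.0)
        assert bd.cf_total == pytest.approx(8.30, abs=1e-12)
        assert bd.cf_per_kg == pytest.approx(8.30, abs=1e-12)

    def test_all_zero(self):
        assert total_footprint(0, 0, 0, 0, 0, live_weight=10.0).cf_total == 0.0

    def test_homogeneity(self):
        bd = total_footprint(100.0, 20.0, 30.0, 40.0, 10.0, live_weight=50.0)
        bd2 = total_footprint(200.0, 40.0, 60.0, 80.0, 20.0, live_weight=100.0)
        assert bd2.cf_total == pytest.approx(2 * bd.cf_total)
        assert bd2.cf_per_kg == pytest.approx(bd.cf_per_kg)

    def test_nonpositive_live_weight_rejected(self):
        with pytest.raises(ValueError):
            total_footprint(1, 1, 1, 1, 1, live_weight=0.0)


class TestFactorValidation:
    def test_negative_factor_is_hard_error(self):
        with pytest.raises(UnitError):
            EmissionFactorSet(enteric_baseline=-1.0)

    def test_rate_above_one_is_hard_error(self):
        with pytest.raises(UnitError, match="fraction"):
            EmissionFactorSet(leaching_rate_manure=1.5)

    def test_electricity_unit_mixup_detected(self):
        with pytest.raises(UnitError, match="MWh"):
            EmissionFactorSet(energy_cf={"electricity": 880.0, "coal": 2.05, "diesel": 3.18})

    def test_yaml_roundtrip(self, tmp_path):
        F.to_yaml(tmp_path / "f.yaml")
        back = EmissionFactorSet.from_yaml(tmp_path / "f.yaml")
        assert back.feed_cf_per_kg["corn"] == F.feed_cf_per_kg["corn"]
        assert back.gwp["N2O"] == 298


class TestLedgerStructure:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            ManureRecord("x", 1.0, {"Solid Storage": 0.5})

    def test_full_footprint_additivity(self):
        a = make_ledger(feed_corn_t=5.0, elec_mwh=2.0, n_kg=40.0, live_out=800.0)
        b = make_ledger(feed_corn_t=7.0, elec_mwh=3.0, n_kg=60.0, live_out=1200.0)
        merged = ActivityLedger(
            feed_tonnes_by_breed={"Landrace": {"corn": 12.0}},
            transport_legs=a.transport_legs + b.transport_legs,
            inventory=a.inventory + b.inventory,
            energy_use={"electricity": 5.0},
            manure=a.manure + b.manure,
            total_live_weight_kg=2000.0,
        )
        bd_a = footprint_from_ledger(a, F)
        bd_b = footprint_from_ledger(b, F)
        bd_m = footprint_from_ledger(merged, F)
        assert bd_m.cf_total == pytest.approx(bd_a.cf_total + bd_b.cf_total)


def test_sem_is_sd_over_sqrt_n():
    vals = [8.1, 8.5, 8.0, 8.4]
    assert sem(vals) == pytest.approx(np.std(vals, ddof=1) / 2.0)
    with pytest.raises(ValueError):
        sem([1.0])
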