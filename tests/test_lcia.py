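"""Inventory assembly and linear midpoint characterization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from piglca.emissions import GasEmissions
from piglca.farm_inputs import FarmInputs
from piglca.lcia import (LifeCycleInventory, ImpactVector, CharacterizationTable,
                         FeedImpactTable, assemble_inventory, characterize,
                         contribution, CharacterizationError, CATEGORIES)
from piglca.pipeline import pig_lca


def _mini_tables():
    cf = CharacterizationTable(factors={
        "ch4": {"CC": 34.0}, "n2o": {"CC": 298.0}, "nh3": {"AP": 1.96},
        "water": {"WD": 0.001}, "n_leached": {}, "p_freshwater": {"EP": 1.0},
        "fert_n": {"CC": 3.6},
    })
    feed_cf = FeedImpactTable(factors={
        "wheat": {"CC": 0.6, "AP": 0.008, "EP": 3e-4, "LO": 1.8, "WD": 0.02},
        "soy": {"CC": 2.2, "AP": 0.009, "EP": 4.5e-4, "LO": 3.6, "WD": 0.012}})
    return cf, feed_cf


def _lci(flows):
    inv = LifeCycleInventory()
    for name, (amount, unit) in flows.items():
        inv.add(name, amount, unit)
    return inv


class TestAssemble:
    def _args(self, lw=115.0, scale=1.0):
        gases = [GasEmissions(phase="enteric", CH4=1.5 * scale),
                 GasEmissions(phase="housing", NH3=0.9 * scale)]
        field = {"N_leached": 0.5 * scale, "P_to_freshwater": 0.1 * scale}
        credit = {"N": 2.0 * scale, "P": 0.5 * scale, "K": 1.0 * scale}
        farm = FarmInputs(drinking_water_l=600 * scale,
                          cleaning_water_l=30 * scale,
                          electricity_kwh=30 * scale, oil_kwh=10 * scale,
                          gas_kwh=5 * scale, transport_tkm=20 * scale)
        return dict(feed_kg_by_ingredient={"wheat": 200.0 * scale,
                                           "soy": 44.0 * scale},
                    gas_emissions=gases, field=field, credit=credit,
                    farm=farm, slaughter_lw=lw)

    def test_planted_flows_normalized(self):
        inv = assemble_inventory(**self._args())
        assert inv.amount("feed:wheat") == pytest.approx(200.0 / 115.0)
        assert inv.amount("ch4@enteric") == pytest.approx(1.5 / 115.0)
        assert inv.amount("credit:fert_n") == pytest.approx(2.0 / 115.0)
        assert inv.amount("water") == pytest.approx(630.0 / 115.0)

    def test_homogeneity(self):
        # doubling all absolute flows and the LW leaves the inventory unchanged
        a = assemble_inventory(**self._args())
        b = assemble_inventory(**self._args(lw=230.0, scale=2.0))
        for name, (amount, _) in a.flows.items():
            assert b.amount(name) == pytest.approx(amount)

    def test_missing_stage_rejected(self):
        args = self._args()
        args["field"] = None
        with pytest.raises(ValueError, match="field"):
            assemble_inventory(**args)

    def test_nonpositive_lw_rejected(self):
        with pytest.raises(ValueError):
            assemble_inventory(**self._args(lw=0.0))


class TestCharacterize:
    def test_single_flow(self):
        cf, feed_cf = _mini_tables()
        v = characterize(_lci({"ch4@storage": (1.0, "kg")}), cf, feed_cf)
        assert v.CC == pytest.approx(34.0)
        assert v.AP == v.EP == v.LO == v.WD == 0.0

    def test_empty_inventory(self):
        cf, feed_cf = _mini_tables()
        v = characterize(LifeCycleInventory(), cf, feed_cf)
        assert v.as_dict() == {c: 0.0 for c in CATEGORIES}

    def test_credit_subtracts(self):
        cf, feed_cf = _mini_tables()
        v = characterize(_lci({"credit:fert_n": (2.0, "kg")}), cf, feed_cf)
        assert v.CC == pytest.approx(-7.2)

    def test_unmapped_flow_listed(self):
        cf, feed_cf = _mini_tables()
        with pytest.raises(CharacterizationError, match="mystery"):
            characterize(_lci({"mystery": (1.0, "kg")}), cf, feed_cf)

    def test_matrix_product_oracle(self):
        # dense matrix multiply as the independent route
        cf, feed_cf = _mini_tables()
        flows = {"ch4@storage": (1.3, "kg"), "n2o@storage": (0.05, "kg"),
                 "nh3@housing": (0.8, "kg"), "water": (700.0, "L"),
                 "feed:wheat": (2.0, "kg"), "feed:soy": (0.4, "kg"),
                 "credit:fert_n": (1.5, "kg")}
        rows = {**cf.factors, **{f"feed:{k}": v for k, v in feed_cf.factors.items()}}
        names = list(flows)

        def base(n):
            return "fert_n" if n == "credit:fert_n" else n.split("@")[0]

        A = np.array([[rows[base(n)].get(c, 0.0) for c in CATEGORIES]
                      for n in names])
        x = np.array([flows[n][0] * (-1.0 if n.startswith("credit:") else 1.0)
                      for n in names])
        expected = x @ A
        v = characterize(_lci(flows), cf, feed_cf)
        assert np.allclose(list(v.as_dict().values()), expected)

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.1, 3.0),
           st.floats(0.1, 3.0))
    @settings(max_examples=40, deadline=None)
    def test_linearity_property(self, m1, m2, a, b):
        cf, feed_cf = _mini_tables()
        l1 = _lci({"ch4@storage": (m1, "kg"), "feed:wheat": (m2, "kg")})
        l2 = _lci({"nh3@housing": (m2, "kg"), "feed:soy": (m1, "kg")})
        combo = _lci({"ch4@storage": (a * m1, "kg"), "feed:wheat": (a * m2, "kg"),
                      "nh3@housing": (b * m2, "kg"), "feed:soy": (b * m1, "kg")})
        v1 = characterize(l1, cf, feed_cf).as_dict()
        v2 = characterize(l2, cf, feed_cf).as_dict()
        vc = characterize(combo, cf, feed_cf).as_dict()
        for c in CATEGORIES:
            assert vc[c] == pytest.approx(a * v1[c] + b * v2[c], abs=1e-9)


class TestContribution:
    def test_single_segment_is_100(self):
        cf, feed_cf = _mini_tables()
        br = contribution(_lci({"feed:wheat": (2.0, "kg")}), cf, feed_cf)
        assert br.shares["CC"]["feed"] == pytest.approx(100.0)
        assert br.shares["CC"]["housing_and_manure"] == 0.0

    def test_shares_sum_to_100(self, fx, mean_pigs):
        _, traj, traits = mean_pigs["HRFI"]
        res = pig_lca(traj, traits, fx)
        br = contribution(res.inventory, fx.characterization, fx.feed_impacts)
        for c in CATEGORIES:
            assert sum(br.shares[c].values()) == pytest.approx(100.0, abs=1e-6)

    def test_land_occupation_is_all_feed(self, fx, mean_pigs):
        # fixtures assign LO to feed ingredients only
        _, traj, traits = mean_pigs["HRFI"]
        res = pig_lca(traj, traits, fx)
        br = contribution(res.inventory, fx.characterization, fx.feed_impacts)
        assert br.shares["LO"]["feed"] == pytest.approx(100.0, abs=1e-9)

    def test_two_segment_hand_shares(self):
        cf, feed_cf = _mini_tables()
        lci = _lci({"feed:wheat": (1.0, "kg"), "ch4@storage": (1.0, "kg")})
        br = contribution(lci, cf, feed_cf)
        assert br.shares["CC"]["feed"] == pytest.approx(100 * 0.6 / 34.6)
        assert br.shares["CC"]["housing_and_manure"] == pytest.approx(
            100 * 34.0 / 34.6)

    def test_zero_total_category_rejected(self):
        cf, feed_cf = _mini_tables()
        with pytest.raises(CharacterizationError, match="zero"):
            contribution(_lci({"ch4@storage": (1.0, "kg")}), cf, feed_cf)


def test_impact_vector_arithmetic():
    a = ImpactVector(CC=1.0, AP=0.5)
    b = ImpactVector(CC=2.0, WD=0.1)
    assert (a + b).CC == 3.0
    assert a.scale(2.0).AP == 1.0
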