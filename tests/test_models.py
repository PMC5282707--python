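"""Model I/O, exchange detection, balance checking, growth calibration."""

import json

import numpy as np
import pytest

import batchprod as bp
from batchprod.models import (
    BoundaryMap, CalibrationError, ConfigurationError, FormatError,
    MetabolicNetwork, calibrate_growth_energetics, check_balances, fba,
    growth_yield, read_network, write_network,
)


class TestReadNetwork:
    def test_toy_linear_structure(self):
        net = read_network(bp.fixture_path("toy_linear.json"))
        assert len(net.reaction_ids) == 3
        assert set(net.exchange_ids) == {"EX_A", "EX_B"}
        assert len(set(net.reaction_ids) - set(net.exchange_ids)) == 1

    def test_core_fixture_boundary_species(self, a_succ):
        net, boundary = a_succ
        assert set(net.exchange_ids) == {
            "EX_glc", "EX_succ", "EX_for", "EX_ac", "EX_pyr", "EX_co2",
            "EX_biomass"}
        assert net.biomass_id == "BIOMASS"
        assert net.atp_demand_id == "ATPM"
        # boundary species: biomass, ATP, glucose and the fermentation
        # products; CO2 is a free exchange not part of the yield space
        assert boundary.species == ["biomass", "atp", "glc", "succ", "for",
                                    "ac", "pyr"]
        assert boundary.species[0] == "biomass"
        assert "co2" not in boundary.species

    def test_zero_reactions_is_format_error(self, tmp_path):
        p = tmp_path / "empty.json"
        p.write_text(json.dumps({"metabolites": [], "reactions": [],
                                 "biomass_id": None}))
        with pytest.raises(FormatError):
            read_network(p)

    def test_invalid_json_is_format_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(FormatError):
            read_network(p)

    def test_missing_biomass_is_configuration_error(self, tmp_path):
        p = tmp_path / "nobio.json"
        p.write_text(json.dumps({
            "metabolites": ["A"],
            "reactions": [{"id": "EX_A", "stoichiometry": {"A": -1}}]}))
        with pytest.raises(ConfigurationError, match="biomass"):
            read_network(p)

    def test_json_round_trip_exact(self, a_succ, tmp_path):
        net, boundary = a_succ
        out = tmp_path / "rt.json"
        write_network(net, out, boundary)
        net2 = read_network(out)
        assert net2.reaction_ids == net.reaction_ids
        assert net2.metabolite_ids == net.metabolite_ids
        np.testing.assert_array_equal(net2.stoich, net.stoich)
        np.testing.assert_array_equal(net2.reversible, net.reversible)

    def test_sbml_round_trip_via_cobra(self, tmp_path):
        import cobra

        model = cobra.Model("m")
        a = cobra.Metabolite("A", compartment="c")
        b = cobra.Metabolite("B", compartment="c")
        conv = cobra.Reaction("CONV", lower_bound=0, upper_bound=1000)
        conv.add_metabolites({a: -1, b: 1})
        ex_a = cobra.Reaction("EX_A", lower_bound=-1000, upper_bound=1000)
        ex_a.add_metabolites({a: -1})
        ex_b = cobra.Reaction("EX_B", lower_bound=0, upper_bound=1000)
        ex_b.add_metabolites({b: -1})
        model.add_reactions([conv, ex_a, ex_b])
        model.objective = "CONV"
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(model, str(path))
        net = read_network(path, format="sbml")
        assert set(net.reaction_ids) == {"CONV", "EX_A", "EX_B"}
        assert set(net.exchange_ids) == {"EX_A", "EX_B"}
        assert net.biomass_id == "CONV"
        j = net.rxn_index("CONV")
        assert net.stoich[net.met_index("A"), j] == -1


class TestBoundaryMap:
    def test_biomass_must_be_first(self):
        with pytest.raises(ConfigurationError, match="species\\[0\\]"):
            BoundaryMap(species=["glc", "biomass"],
                        exchange_of={"glc": "EX_glc", "biomass": "EX_b"},
                        units_of={"biomass": "gDCW/L", "glc": "mM"},
                        product_species="biomass", substrate_species="glc")

    def test_product_substrate_distinct(self):
        with pytest.raises(ConfigurationError, match="distinct"):
            BoundaryMap(species=["glc"], exchange_of={"glc": "EX_glc"},
                        units_of={"glc": "mM"},
                        product_species="glc", substrate_species="glc")


class TestCheckBalances:
    def test_core_fixture_is_carbon_balanced(self, a_succ, a_succ_formulas):
        net, _ = a_succ
        report = check_balances(net, a_succ_formulas)
        assert report.unbalanced == []
        assert report.uncheckable == []

    def test_corrupted_coefficient_is_flagged(self, a_succ, a_succ_formulas):
        net, _ = a_succ
        bad = net.copy()
        j = bad.rxn_index("FRD")
        bad.stoich[bad.met_index("succ"), j] = 2.0  # seeded defect
        report = check_balances(bad, a_succ_formulas)
        assert [r[0] for r in report.unbalanced] == ["FRD"]
        assert report.unbalanced[0][1] == "C"
        assert report.unbalanced[0][2] == pytest.approx(4.0)

    def test_empty_formula_map_all_uncheckable(self, a_succ):
        net, _ = a_succ
        report = check_balances(net, {})
        n_internal = len(net.reaction_ids) - len(net.exchange_ids)
        assert len(report.uncheckable) == n_internal
        assert report.unbalanced == []


def _analytic_toy():
    """Two-pathway toy with closed-form biomass yield 1/(1+g) where g is the
    growth-ATP coefficient: glucose either fuels catabolism (1 ATP each) or
    is built into biomass at a cost of g ATP."""
    mets = ["glc", "atp", "adp", "bio"]
    rxns = [
        ("EX_glc", {"glc": -1}, True),
        ("CAT", {"glc": -1, "adp": -1, "atp": 1}, False),
        ("GROWTH", {"glc": -1, "atp": -2.0, "adp": 2.0, "bio": 1}, False),
        ("ATPM", {"atp": -1, "adp": 1}, False),
        ("EX_bio", {"bio": -1}, False),
    ]
    mi = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxns)))
    ids, rev = [], []
    for j, (rid, st, r) in enumerate(rxns):
        ids.append(rid)
        rev.append(r)
        for m, c in st.items():
            S[mi[m], j] = c
    net = MetabolicNetwork(ids, mets, S, np.array(rev),
                           biomass_id="GROWTH", atp_demand_id="ATPM")
    boundary = BoundaryMap(
        species=["bio", "atp", "glc"],
        exchange_of={"bio": "EX_bio", "atp": "ATPM", "glc": "EX_glc"},
        units_of={"bio": "gDCW/L", "glc": "mM"},
        product_species="bio", substrate_species="glc",
        flux_only={"atp"})
    return net, boundary


class TestCalibration:
    def test_core_fixture_reproduces_measured_yield(self, a_succ):
        """mu/uptake = 0.414/9.5 rounds to 0.044 gDCW per mmol glucose, and
        the shipped fixture's growth LP reproduces it within 1%."""
        assert round(0.414 / 9.5, 3) == 0.044
        net, boundary = a_succ
        y = growth_yield(net, boundary, uptake_rate=9.5, maintenance=4.7)
        assert y == pytest.approx(0.044, rel=0.01)

    def test_calibration_matches_closed_form(self):
        net, boundary = _analytic_toy()
        target = 0.25  # => g = 1/y - 1 = 3
        cal = calibrate_growth_energetics(net, boundary, target, uptake_rate=5.0)
        g = -cal.stoich[cal.met_index("atp"), cal.rxn_index("GROWTH")]
        assert g == pytest.approx(1.0 / target - 1.0, rel=1e-3)
        assert growth_yield(cal, boundary, 5.0) == pytest.approx(target, rel=1e-3)
        # original network untouched
        assert net.stoich[net.met_index("atp"), net.rxn_index("GROWTH")] == -2.0

    def test_calibration_is_idempotent(self, a_succ):
        net, boundary = a_succ
        cal1 = calibrate_growth_energetics(net, boundary, 0.044, 9.5,
                                           maintenance=4.7)
        cal2 = calibrate_growth_energetics(cal1, boundary, 0.044, 9.5,
                                           maintenance=4.7)
        g1 = -cal1.stoich[cal1.met_index("atp"), cal1.rxn_index("BIOMASS")]
        g2 = -cal2.stoich[cal2.met_index("atp"), cal2.rxn_index("BIOMASS")]
        assert abs(g1 - g2) < 1e-6

    def test_infeasible_target_reports_maximum(self, a_succ):
        net, boundary = a_succ
        with pytest.raises(CalibrationError) as exc:
            calibrate_growth_energetics(net, boundary, 0.5, 9.5)
        assert exc.value.max_achievable is not None
        assert 0 < exc.value.max_achievable < 0.5

    def test_zero_target_drives_coefficient_to_bound(self, a_succ):
        net, boundary = a_succ
        cal = calibrate_growth_energetics(net, boundary, 0.0, 9.5,
                                          coeff_max=300.0)
        g = -cal.stoich[cal.met_index("atp"), cal.rxn_index("BIOMASS")]
        assert g == pytest.approx(300.0)


class TestSteadyStateLP:
    def test_max_succinate_yield_is_12_over_7(self, a_succ):
        """With CO2 fixation permitted and maintenance disabled the core
        network reaches the classic 12/7 mol succinate per mol glucose."""
        net, boundary = a_succ
        y = bp.max_product_yield(net, boundary, maintenance=0.0)
        assert y == pytest.approx(12.0 / 7.0, abs=1e-9)
        assert round(y, 2) == 1.71

    def test_cross_check_against_cobra(self, a_succ):
        """Independent LP route: the same optimum from cobra/GLPK."""
        import cobra

        net, boundary = a_succ
        model = cobra.Model("core")
        mets = {m: cobra.Metabolite(m, compartment="c")
                for m in net.metabolite_ids}
        rxns = []
        for j, rid in enumerate(net.reaction_ids):
            r = cobra.Reaction(rid,
                               lower_bound=-1000 if net.reversible[j] else 0,
                               upper_bound=1000)
            col = net.stoich[:, j]
            r.add_metabolites({mets[net.metabolite_ids[i]]: col[i]
                               for i in np.flatnonzero(col)})
            rxns.append(r)
        model.add_reactions(rxns)
        # cobra treats single-metabolite reactions as boundary; the
        # metabolites must not be re-balanced
        model.reactions.EX_glc.bounds = (-1.0, -1.0)
        model.objective = "EX_succ"
        sol = model.optimize()
        assert sol.objective_value == pytest.approx(12.0 / 7.0, abs=1e-6)

    def test_maintenance_lowers_succinate_yield(self, a_succ):
        net, boundary = a_succ
        y0 = bp.max_product_yield(net, boundary, maintenance=0.0)
        # maintenance forces ATP production per unit glucose; at unit uptake
        # a demand of 0.5 mmol/mmol glc must come from somewhere
        glc_ex = boundary.exchange_of["glc"]
        y1 = fba(net, "EX_succ", fixed={glc_ex: -1.0}, lower={"ATPM": 0.5})
        assert y1 <= y0 + 1e-9
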