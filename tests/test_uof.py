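import dataclasses
import math

import pytest

import uofba as u
from uofba.lp_engine import InfeasibleProblem, check_mass_balance
from oracle import oracle_fba
from conftest import MU, QP


class TestCorrection:
    def _enm(self, values):
        return u.ENMResult(growth_rate=MU, productivity=0.0,
                           minimal_uptake=values,
                           essential_ids={k for k, v in values.items() if v > 1e-6})

    def test_underestimated_measurement_replaced(self):
        enm = self._enm({"EX_lys": 0.010})
        profile = u.ExchangeProfile(MU, 0.0, {"EX_lys": 0.008}, {"EX_lys"})
        corrected, log = u.correct_essential_constraints(profile, enm)
        assert corrected.measured_rates["EX_lys"] == pytest.approx(0.010)
        (entry,) = log
        assert entry.action == "replaced"
        assert entry.magnitude == pytest.approx(0.002)

    def test_sufficient_measurement_kept(self):
        enm = self._enm({"EX_lys": 0.010})
        profile = u.ExchangeProfile(MU, 0.0, {"EX_lys": 0.012}, {"EX_lys"})
        corrected, log = u.correct_essential_constraints(profile, enm)
        assert corrected.measured_rates["EX_lys"] == pytest.approx(0.012)
        assert log[0].action == "kept"

    def test_missing_essentials_imputed(self):
        enm = self._enm({"EX_lys": 0.010, "EX_his": 0.005})
        profile = u.ExchangeProfile(MU, 0.0, {}, {"EX_lys", "EX_his"})
        corrected, log = u.correct_essential_constraints(profile, enm)
        assert {e.action for e in log} == {"imputed"}
        assert corrected.measured_rates == pytest.approx(
            {"EX_lys": 0.010, "EX_his": 0.005})

    def test_nonessential_rates_untouched(self):
        enm = self._enm({"EX_lys": 0.010})
        profile = u.ExchangeProfile(MU, 0.0, {"EX_lys": 0.02, "EX_glc": 1.0}, {"EX_lys"})
        corrected, _ = u.correct_essential_constraints(profile, enm)
        assert corrected.measured_rates["EX_glc"] == 1.0


class TestMinimize:
    def test_hypothetical_network2_min_c_is_two(self, net2):
        """With X production pinned at 4 and A, B availabilities measured,
        surplus B converts to C and only 2 units of C must be imported."""
        profile = u.ExchangeProfile(4.0, 0.0, {"EX_A": 4.0, "EX_B": 6.0, "EX_C": 8.0})
        minimized, sol = u.uof_minimize(net2, profile, "EX_C")
        assert minimized == pytest.approx(2.0, abs=1e-9)
        _, z, _ = oracle_fba(net2, "EX_C",
                             equalities={"EX_X": 4.0, "EX_A": -4.0, "EX_B": -6.0},
                             overrides={"EX_C": (-1e3, 1000.0)})
        assert minimized == pytest.approx(-z, abs=1e-9)

    def test_minimized_never_exceeds_feasible_measured(self, toy, toy_profile, toy_enm):
        res = u.uof_sweep(toy, toy_profile, toy_enm)
        for rid, v in res.minimized_uptake.items():
            assert v <= toy_profile.measured_rates[rid] + 1e-9

    def test_target_measurement_is_excluded_from_constraints(self, toy, toy_profile, toy_enm):
        """The solved-for flux must not constrain itself: distorting the
        target's own measured value leaves the minimum unchanged."""
        distorted = dataclasses.replace(
            toy_profile,
            measured_rates={**toy_profile.measured_rates,
                            "EX_glc": toy_profile.measured_rates["EX_glc"] * 5},
        )
        base, _ = u.uof_minimize(toy, toy_profile, "EX_glc")
        alt, _ = u.uof_minimize(toy, distorted, "EX_glc")
        assert alt == pytest.approx(base, abs=1e-9)

    def test_unconsumed_target_needs_forcing(self, toy, toy_profile):
        with pytest.raises(ValueError, match="not consumed"):
            u.uof_minimize(toy, toy_profile, "EX_tyr")
        minimized, _ = u.uof_minimize(toy, toy_profile, "EX_tyr", forced=True)
        assert minimized >= 0.0

    def test_infeasible_without_enm_correction(self, toy, toy_profile):
        """An underestimated essential uptake makes the pinned constraint set
        infeasible, and the diagnosis names the bad measurement — correcting
        with ENM restores feasibility (the whole point of the correction)."""
        bad_rates = dict(toy_profile.measured_rates)
        bad_rates["EX_lys"] *= 0.5
        bad = dataclasses.replace(toy_profile, measured_rates=bad_rates)
        with pytest.raises(InfeasibleProblem) as err:
            u.uof_minimize(toy, bad, "EX_glc")
        diag = dict(err.value.diagnosis)
        assert "EX_lys" in diag
        # internal sign: the pinned export flux must drop (more uptake)
        assert diag["EX_lys"] == pytest.approx(
            -(toy_profile.measured_rates["EX_lys"] - bad_rates["EX_lys"]), abs=1e-6)
        enm = u.enm_sweep(toy, MU, QP)
        res = u.uof_sweep(toy, bad, enm)
        assert res.statuses["EX_glc"] == "optimal"
        assert any(e.action == "replaced" and e.exchange_id == "EX_lys"
                   for e in res.correction_log)


class TestSweep:
    def test_forward_profile_recovered_exactly(self, toy, toy_profile, toy_enm):
        """On a self-consistent forward-simulated profile every minimized
        uptake equals the generating rate."""
        res = u.uof_sweep(toy, toy_profile, toy_enm)
        assert res.statuses and all(s == "optimal" for s in res.statuses.values())
        for rid, v in res.minimized_uptake.items():
            assert v == pytest.approx(toy_profile.measured_rates[rid], abs=1e-6), rid

    def test_raised_byproduct_secretion_raises_glucose_minimum(self, toy, toy_profile, toy_enm):
        """Extra lactate secretion must be fed by extra glucose (overflow
        metabolism bookkeeping: 1 glucose per 2 lactate, minus the ATP the
        glycolytic route contributes)."""
        rates = dict(toy_profile.measured_rates)
        rates["EX_lac"] -= 0.02  # secretion is negative in user space
        pushed = dataclasses.replace(toy_profile, measured_rates=rates)
        base, _ = u.uof_minimize(toy, toy_profile, "EX_glc")
        more, _ = u.uof_minimize(toy, pushed, "EX_glc")
        assert more > base
        # 0.02 extra lactate: +0.01 glycolysis, whose 0.02 ATP frees 0.002
        # respiratory glucose
        assert more - base == pytest.approx(0.01 - 0.002, rel=1e-6)

    def test_sweep_with_no_consumed_targets_is_empty(self, net1):
        profile = u.ExchangeProfile(0.0, 0.0, {"EX_A": 0.0})
        enm = u.ENMResult(0.0, 0.0, {}, set())
        res = u.uof_sweep(net1, profile, enm)
        assert res.minimized_uptake == {} and res.statuses == {}

    def test_conversion_reaction_never_increases_minimized_uptake(self, net1, net2):
        """The interconversion-augmented network needs no more of any
        component than the base network (metabolic flexibility is monotone),
        and strictly less C once surplus B is pinned."""
        profile = u.ExchangeProfile(4.0, 0.0, {"EX_A": 4.0, "EX_B": 4.0})
        for target in ("EX_A", "EX_B", "EX_C", "EX_D"):
            m1, _ = u.uof_minimize(net1, profile, target, forced=True)
            m2, _ = u.uof_minimize(net2, profile, target, forced=True)
            assert m2 <= m1 + 1e-9, target
        surplus_b = u.ExchangeProfile(4.0, 0.0, {"EX_A": 4.0, "EX_B": 6.0})
        m2, _ = u.uof_minimize(net2, surplus_b, "EX_C", forced=True)
        m1, _ = u.uof_minimize(net1, profile, "EX_C", forced=True)
        assert m2 == pytest.approx(2.0, abs=1e-9)
        assert m1 == pytest.approx(4.0, abs=1e-9)

    def test_variant_models_distinguished_by_uof_not_bof(self, toy, toy_profile, toy_enm):
        """Two cell-line variants differing by one conversion reaction give
        identical growth-maximization answers but different minimized
        tyrosine uptakes once a phenylalanine surplus exists."""
        variant = u.MetabolicModel(
            "toy_no_phe_tyr",
            list(toy.metabolites),
            [r for r in toy.reactions if r.id != "PHE_TYR"]
            + [u.Reaction("SYN_tyr", {"glc": -1.0, "atp": -1.0, "tyr": 2.0,
                                      "adp": 1.0, "pi": 1.0})],
            biomass_reaction_id=toy.biomass_reaction_id,
            product_reaction_id=toy.product_reaction_id,
            notes=dict(toy.notes),
        )
        prof = toy_profile  # its phe uptake already covers the tyr demand 1:1
        # with glucose headroom both variants hit the same essential-amino
        # ceiling: the growth maximization answers are indistinguishable
        bof_prof = dataclasses.replace(
            prof, measured_rates={**prof.measured_rates,
                                  "EX_glc": prof.measured_rates["EX_glc"] + 1.0})
        mu_a, _ = u.predict_growth_bof(toy, bof_prof)
        mu_b, _ = u.predict_growth_bof(variant, bof_prof)
        assert mu_a == pytest.approx(mu_b, rel=1e-9)
        tyr_a, _ = u.uof_minimize(toy, prof, "EX_tyr", forced=True)
        tyr_b, _ = u.uof_minimize(variant, prof, "EX_tyr", forced=True)
        assert tyr_a < tyr_b  # phe substitutes tyr only via the conversion
        tyr_demand = toy.notes["biomass_coefficients"]["tyr"] * MU
        assert tyr_b - tyr_a == pytest.approx(tyr_demand, rel=1e-6)

    def test_mass_balance_audited_at_every_optimum(self, toy, toy_profile, toy_enm):
        res = u.uof_sweep(toy, toy_profile, toy_enm)
        for rid, sol in res.solutions.items():
            assert check_mass_balance(toy, sol.fluxes) < 1e-6, rid


class TestDualMatrix:
    def test_tyrosine_row_is_phenylalanine_substitution(self, toy, toy_profile_slack, toy_enm):
        """Tyrosine's only internal source is 1:1 conversion from
        phenylalanine: its dual-price row is exactly {phe: -1, tyr: -1}."""
        perturb = sorted(toy_profile_slack.measured_rates)
        res = u.uof_dual_matrix(toy, toy_profile_slack, toy_enm, perturb,
                                objective_ids=["EX_tyr"])
        row = {j: res.dual_matrix[("EX_tyr", j)] for j in perturb}
        nonzero = {j for j, v in row.items() if abs(v) > 1e-6}
        assert nonzero == {"EX_phe", "EX_tyr"}
        assert row["EX_phe"] == pytest.approx(-1.0, abs=1e-6)
        assert row["EX_tyr"] == pytest.approx(-1.0, abs=1e-6)
        assert not res.failed_duals

    def test_unrelated_nutrient_column_is_zero(self, toy, toy_profile_slack, toy_enm):
        """Tryptophan links to no other nutrient's requirement: its column
        vanishes in every row."""
        res = u.uof_dual_matrix(toy, toy_profile_slack, toy_enm, ["EX_trp"],
                                objective_ids=["EX_glc", "EX_asp", "EX_glu", "EX_tyr"])
        for key, v in res.dual_matrix.items():
            assert v == pytest.approx(0.0, abs=1e-6), key

    def test_methionine_surplus_burdens_other_uptakes(self, toy, toy_profile, toy_enm):
        """Forced methionine catabolism consumes serine and ATP, so extra
        methionine raises the serine and glucose requirements.  Stoichiometry
        of the fixture: serine +1 via uptake plus the ATP books, glucose
        0.5 (synthesis) + 0.25 (respiration for 2.5 ATP) = +0.75."""
        res = u.uof_dual_matrix(toy, toy_profile, toy_enm, ["EX_met"],
                                objective_ids=["EX_glc", "EX_ser"])
        assert res.dual_matrix[("EX_glc", "EX_met")] == pytest.approx(0.75, abs=1e-6)
        assert res.dual_matrix[("EX_ser", "EX_met")] > 0.5

    def test_unabsorbable_perturbation_is_flagged_not_fatal(self, toy, toy_profile, toy_enm):
        """In a fully pinned scenario an aspartate objective cannot absorb a
        methionine surplus in either direction: the entry is NaN and
        flagged, the rest of the matrix is still produced."""
        res = u.uof_dual_matrix(toy, toy_profile, toy_enm, ["EX_met", "EX_asp"],
                                objective_ids=["EX_asp"])
        assert ("EX_asp", "EX_met") in res.failed_duals
        assert math.isnan(res.dual_matrix[("EX_asp", "EX_met")])
        assert res.dual_matrix[("EX_asp", "EX_asp")] == pytest.approx(-1.0, abs=1e-6)

    def test_diagonal_never_positive(self, toy, toy_profile_slack, toy_enm):
        """More availability of a nutrient never increases its own minimal
        requirement."""
        res = u.uof_dual_matrix(toy, toy_profile_slack, toy_enm,
                                ["EX_glc", "EX_asp", "EX_glu"],
                                objective_ids=["EX_glc", "EX_asp", "EX_glu"])
        for rid in ("EX_glc", "EX_asp", "EX_glu"):
            assert res.dual_matrix[(rid, rid)] <= 1e-9


class TestFVA:
    def test_uof_ranges_subset_of_bof_ranges(self, toy, toy_profile, toy_enm):
        """With the profile self-consistent, the UOF feasible set (growth and
        all exchanges pinned) sits inside the BOF feasible set (uptake caps
        only), so every UOF flux range nests inside the BOF one."""
        reactions = ["GLYC", "RESP", "OX_WASTE", "SYN_ser", "ATPM"]
        uof_ranges = u.uof_fva(toy, toy_profile, "EX_glc", reactions, enm=toy_enm)
        mu_star, _ = u.predict_growth_bof(toy, toy_profile)
        from uofba.bof_analysis import _bof_spec

        bof_ranges = u.flux_variability(_bof_spec(toy, toy_profile), reactions,
                                        fix_objective_at=mu_star)
        for rid in reactions:
            u_lo, u_hi = uof_ranges[rid]
            b_lo, b_hi = bof_ranges[rid]
            assert b_lo - 1e-7 <= u_lo and u_hi <= b_hi + 1e-7, rid

    def test_fully_determined_reaction_has_zero_width(self, toy, toy_profile, toy_enm):
        """Pinned lactate secretion pins the glycolytic flux exactly."""
        ranges = u.uof_fva(toy, toy_profile, "EX_glc", ["GLYC"], enm=toy_enm)
        lo, hi = ranges["GLYC"]
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_dropping_growth_constraint_widens_ranges(self, net2):
        spec_pinned = u.LPSpec(net2, "EX_C", "maximize", {"EX_X": 4.0})
        sol = u.solve(spec_pinned)
        pinned = u.flux_variability(spec_pinned, ["EX_B", "BC_CONV"],
                                    fix_objective_at=sol.objective_value)
        spec_free = u.LPSpec(net2, "EX_C", "maximize")
        free = u.flux_variability(spec_free, ["EX_B", "BC_CONV"],
                                  fix_objective_at=sol.objective_value)
        for rid in ("EX_B", "BC_CONV"):
            assert free[rid][0] <= pinned[rid][0] + 1e-9
            assert free[rid][1] >= pinned[rid][1] - 1e-9


class TestProfileIO:
    def test_profile_tsv_round_trip(self, toy_profile, tmp_path):
        p = tmp_path / "profile.tsv"
        u.write_profile(toy_profile, p)
        back = u.read_profile(p)
        assert back.growth_rate == pytest.approx(toy_profile.growth_rate, rel=1e-8)
        assert back.productivity == pytest.approx(toy_profile.productivity, rel=1e-8)
        assert back.essential_ids == toy_profile.essential_ids
        for rid, v in toy_profile.measured_rates.items():
            assert back.measured_rates[rid] == pytest.approx(v, rel=1e-8, abs=1e-12), rid
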