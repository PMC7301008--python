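"""Metabolism modules: stoichiometry, pipeline bookkeeping, variants."""

import numpy as np
import pytest

from hextissue.config import default_cell_params
from hextissue.metabolism import (MetabolismState, S_GLYC, S_OP, S_OXPHOS,
                                  S_PG, cell_surface_area, consume_mass,
                                  energy_demand, finalize_tick,
                                  generate_energy, generate_mass,
                                  glucose_uptake, nutrient_availability,
                                  nutrient_requirements, step_metabolism,
                                  update_energy)


@pytest.fixture
def params():
    return default_cell_params()


def fresh_state(m=2400.0, G=0.0, P=0.0, E=0.0):
    return MetabolismState(G_int=G, P_int=P, E=E, m=m, m_crit=m)


class TestAvailabilityAndDemand:
    def test_zero_concentration_zero_amount(self):
        g, o = nutrient_availability(0.0, 0.0, 6781.0, 1.3e-6)
        assert g == 0.0 and o == 0.0

    def test_amounts_scale_with_volume_and_solubility(self):
        g, o = nutrient_availability(0.004, 80.0, 6781.0, 1.3e-6)
        assert g == pytest.approx(0.004 * 6781.0)
        assert o == pytest.approx(80.0 * 6781.0 * 1.3e-6)

    def test_basal_demand(self, params):
        e_cons, e_req = energy_demand(2000.0, 0, 0, 0.0, params)
        assert e_cons == pytest.approx(2000.0 * params["BASAL_ENERGY"])
        assert e_req == e_cons

    def test_proliferative_flag_adds_energy(self, params):
        base, _ = energy_demand(2000.0, 0, 0, 0.0, params)
        pr, _ = energy_demand(2000.0, 1, 0, 0.0, params)
        assert pr == pytest.approx(base + 2000.0 * params["PROLIF_ENERGY"])

    def test_deficit_carryover(self, params):
        p = dict(params, BASAL_ENERGY=0.01, PROLIF_ENERGY=0, MIGRA_ENERGY=0)
        e_cons, e_req = energy_demand(1000.0, 0, 0, -5.0, p)
        assert e_cons == pytest.approx(10.0)
        assert e_req == pytest.approx(15.0)

    def test_surplus_not_carried(self, params):
        _, e_req = energy_demand(1000.0, 0, 0, +7.0, params)
        assert e_req == pytest.approx(1000.0 * params["BASAL_ENERGY"])


class TestGlucoseUptake:
    @pytest.mark.parametrize("cx", ["simple", "medium", "complex"])
    def test_zero_gradient_zero_uptake(self, cx, params):
        v, V = 2000.0, 6781.0
        st = fresh_state(G=0.004 * v)
        up = glucose_uptake(cx, st, params, 0.004 * V, v, V,
                            np.random.default_rng(0))
        assert up == pytest.approx(0.0, abs=1e-12)

    def test_random_mean_is_one_percent(self, params):
        rng = np.random.default_rng(0)
        ups = [glucose_uptake("random", fresh_state(), params, 100.0,
                              2000.0, 6781.0, rng) for _ in range(20000)]
        assert np.mean(ups) == pytest.approx(1.0, rel=0.02)

    def test_complex_scales_with_surface_area(self, params):
        V = 6781.0
        st1, st2 = fresh_state(), fresh_state()
        up1 = glucose_uptake("complex", st1, params, 0.005 * V, 1000.0, V,
                             np.random.default_rng(0))
        up2 = glucose_uptake("complex", st2, params, 0.005 * V, 4000.0, V,
                             np.random.default_rng(0))
        a1 = cell_surface_area(1000.0, params["MAX_HEIGHT"])
        a2 = cell_surface_area(4000.0, params["MAX_HEIGHT"])
        assert up2 / up1 == pytest.approx(a2 / a1)

    def test_clamped_to_available(self, params):
        st = fresh_state()
        up = glucose_uptake("simple", st, params, 1e-6, 2000.0, 6781.0,
                            np.random.default_rng(0))
        assert up <= 1e-6

    def test_unknown_complexity_raises(self, params):
        with pytest.raises(ValueError):
            glucose_uptake("bogus", fresh_state(), params, 1.0, 1.0, 1.0,
                           np.random.default_rng(0))


class TestRequirements:
    def test_pure_glycolysis_no_oxygen(self, params):
        p = dict(params, META_PREF=1.0)
        for cx in ("simple", "medium", "complex"):
            g, aux, o = nutrient_requirements(cx, p, 10.0, 5.0,
                                              np.random.default_rng(0))
            assert o == pytest.approx(0.0)

    def test_pure_oxphos_complex(self, params):
        p = dict(params, META_PREF=0.0)
        g, p_req, o = nutrient_requirements("complex", p, 15.0, 100.0,
                                            np.random.default_rng(0))
        assert g == pytest.approx(0.0)
        assert p_req == pytest.approx(15.0 / S_OXPHOS)
        assert o == pytest.approx(p_req * S_OP)

    def test_no_oxygen_no_uptake(self, params):
        for cx in ("simple", "medium", "complex"):
            _, _, o = nutrient_requirements(cx, params, 10.0, 0.0,
                                            np.random.default_rng(0))
            assert o == 0.0

    def test_nonpositive_requirement_zeroed(self, params):
        g, aux, o = nutrient_requirements("medium", params, -3.0, 10.0,
                                          np.random.default_rng(0))
        assert g == 0.0 and aux == 0.0 and o == 0.0


class TestGenerateEnergy:
    def test_full_oxidation_yields_32_atp_per_glucose(self):
        # glycolysis (2 ATP + 2 pyruvate), then oxphos of both pyruvates
        st = fresh_state(G=1.0)
        e_glyc, _ = generate_energy("complex", st, g_req=1.0, o_uptake=0.0,
                                    E_cons=0.0)
        assert e_glyc == pytest.approx(S_GLYC)
        assert st.P_int == pytest.approx(S_PG)
        e_ox, o_used = generate_energy("complex", st, g_req=0.0,
                                       o_uptake=S_PG * S_OP, E_cons=0.0)
        assert e_ox == pytest.approx(S_PG * S_OXPHOS)
        assert e_glyc + e_ox == pytest.approx(32.0)

    def test_no_oxygen_glycolysis_only(self):
        st = fresh_state(G=5.0)
        e, o = generate_energy("medium", st, g_req=2.0, o_uptake=0.0,
                               E_cons=0.0)
        assert e == pytest.approx(2.0 * S_GLYC)
        assert o == 0.0

    def test_empty_pools_no_energy(self):
        st = fresh_state(G=0.0, P=0.0)
        e, _ = generate_energy("complex", st, g_req=3.0, o_uptake=5.0,
                               E_cons=0.0)
        assert e == 0.0

    def test_oxygen_limit_corrects_uptake(self):
        # more oxygen offered than internal glucose can use
        st = fresh_state(G=0.5)
        e, o = generate_energy("simple", st, g_req=0.0,
                               o_uptake=100.0, E_cons=0.0)
        assert o == pytest.approx(0.5 * S_PG * S_OP)
        assert st.G_int == 0.0

    def test_hypoxic_compensation_diverts_glucose(self):
        # oxygen-limited medium metabolism covers the deficit with glycolysis
        st = fresh_state(G=10.0, E=0.0)
        e, _ = generate_energy("medium", st, g_req=1.0, o_uptake=0.0,
                               E_cons=8.0)
        assert e == pytest.approx(8.0)  # raised to cover E_cons exactly

    @pytest.mark.parametrize("cx", ["simple", "medium", "complex"])
    def test_monotone_in_oxygen(self, cx):
        energies = []
        for o in (0.0, 0.5, 1.0, 2.0, 4.0):
            st = fresh_state(G=3.0, P=3.0)
            e, _ = generate_energy(cx, st, g_req=1.0, o_uptake=o, E_cons=0.0)
            energies.append(e)
        assert all(b >= a - 1e-12 for a, b in zip(energies, energies[1:]))

    def test_energy_never_exceeds_full_oxidation_bound(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            g0 = rng.uniform(0, 5)
            st = fresh_state(G=g0, P=0.0)
            total = 0.0
            for _ in range(5):
                e, _ = generate_energy("complex", st,
                                       g_req=rng.uniform(0, 3),
                                       o_uptake=rng.uniform(0, 10),
                                       E_cons=rng.uniform(0, 5))
                total += e
            routed = g0 - st.G_int           # glucose through glycolysis
            oxidized = routed - st.P_int / S_PG  # fully oxidized share
            assert total <= S_GLYC * routed + S_OXPHOS * S_PG * oxidized + 1e-9
            # and never more than 32 ATP per glucose available in total
            assert total <= 32.0 * g0 + 1e-9


class TestEnergyUpdate:
    def test_balanced(self):
        st = fresh_state(E=1.5)
        update_energy(st, 10.0, 10.0)
        assert st.E == pytest.approx(1.5)

    def test_deficit(self):
        st = fresh_state(E=0.0)
        update_energy(st, 0.0, 10.0)
        assert st.E == pytest.approx(-10.0)


class TestMassGeneration:
    def test_no_growth_at_critical_mass_simple_random(self, params):
        for cx in ("simple", "random"):
            st = fresh_state(m=2400.0, G=50.0)
            generate_mass(cx, st, params, x_pr=0, rng=np.random.default_rng(0))
            assert st.m == 2400.0

    def test_maintenance_growth_below_099(self, params):
        st = fresh_state(G=10.0)
        st.m = 0.9 * st.m_crit
        dm = generate_mass("complex", st, params, x_pr=0,
                           rng=np.random.default_rng(0))
        assert dm > 0

    def test_complex_lambda_one_leaves_pyruvate(self, params):
        p = dict(params, RATIO_GLUC_TO_PYRU=1.0)
        st = fresh_state(G=10.0, P=7.0)
        st.m = 0.5 * st.m_crit
        generate_mass("complex", st, p, x_pr=1, rng=np.random.default_rng(0))
        assert st.P_int == pytest.approx(7.0)

    def test_medium_mass_gain_matches_glucose_spent(self, params):
        st = fresh_state(G=10.0)
        st.m = 0.5 * st.m_crit
        m0, g0 = st.m, st.G_int
        dm = generate_mass("medium", st, params, x_pr=1,
                           rng=np.random.default_rng(0))
        spent = g0 - st.G_int
        assert dm == pytest.approx(spent / params["MASS_TO_GLUC"])

    def test_no_growth_under_deficit(self, params):
        st = fresh_state(G=10.0, E=-1.0)
        st.m = 0.5 * st.m_crit
        dm = generate_mass("complex", st, params, x_pr=1,
                           rng=np.random.default_rng(0))
        assert dm == 0.0


class TestAutophagy:
    def test_no_trigger_at_critical_mass(self, params):
        st = fresh_state(m=2400.0)
        assert consume_mass("complex", st, params, x_pr=0) == 0.0

    def test_deficit_consumes_mass_credits_glucose(self, params):
        st = fresh_state(m=2400.0, E=-1.0)
        g0 = st.G_int
        consume_mass("medium", st, params, x_pr=1)
        assert st.m == pytest.approx(2400.0 - params["AUTOPHAGY_RATE"])
        assert st.G_int == pytest.approx(
            g0 + params["AUTOPHAGY_RATE"] * params["MASS_TO_GLUC"])

    def test_simple_random_never_autophage(self, params):
        for cx in ("simple", "random"):
            st = fresh_state(m=2400.0, E=-5.0)
            assert consume_mass(cx, st, params, x_pr=0) == 0.0

    def test_oversize_trim_only_when_not_proliferating(self, params):
        st = fresh_state(m=2500.0)
        st.m_crit = 2400.0
        assert consume_mass("complex", st, params, x_pr=1) == 0.0
        assert consume_mass("complex", st, params, x_pr=0) > 0.0


class TestFinalize:
    def test_lactate_loss(self, params):
        p = dict(params, LACTATE_RATE=0.1)
        st = fresh_state(P=10.0)
        finalize_tick("complex", st, p, 0.0, 0.0, 1.0, 1.0)
        assert st.P_int == pytest.approx(9.0)

    def test_full_uptake_zeroes_environment(self, params):
        st = fresh_state()
        _, gf, of = finalize_tick("complex", st, params, 5.0, 0.0, 5.0, 1.0)
        assert gf == pytest.approx(0.0)

    def test_volume_tracks_mass(self, params):
        st = fresh_state(m=2140.0)
        v, _, _ = finalize_tick("simple", st, params, 0.0, 0.0, 1.0, 1.0)
        assert v == pytest.approx(2140.0 / params["CELL_DENSITY"])


def oracle_energy(cx, G, P, g_req, o_up, E_prev, E_cons):
    """Independent transcription of the energy branches.

    Returns (e_ox, e_gl, G', P', corrected o_up).
    """
    if cx == "complex":
        p_o = o_up / S_OP
        if P > p_o:
            e_ox, P = p_o * S_OXPHOS, P - p_o
        else:
            e_ox, o_up, P = P * S_OXPHOS, P * S_OP, 0.0
        g_req = max(g_req, -(E_prev - E_cons + e_ox) / S_GLYC, 0.0)
        if G > g_req:
            e_gl, G, P = g_req * S_GLYC, G - g_req, P + g_req * S_PG
        else:
            e_gl, P, G = G * S_GLYC, P + G * S_PG, 0.0
    else:
        g_o = o_up / (S_PG * S_OP)
        if G > g_o:
            e_ox, G = g_o * S_OXPHOS * S_PG, G - g_o
        else:
            e_ox, o_up, G = G * S_OXPHOS * S_PG, G * S_PG * S_OP, 0.0
        if cx == "medium":
            g_req = max(g_req, -(E_prev - E_cons + e_ox) / S_GLYC, 0.0)
        if G > g_req:
            e_gl, G = g_req * S_GLYC, G - g_req
        else:
            e_gl, G = G * S_GLYC, 0.0
    return e_ox, e_gl, G, P, o_up


class TestCarbonLedger:
    """Glucose-equivalent bookkeeping closes over a full pipeline tick.

    The energy branches are cross-checked against an independent
    transcription, and the carbon ledger (pools + uptake + autophagy in;
    mass + lactate + oxidized/fermented carbon out) must balance.
    """

    @pytest.mark.parametrize("cx", ["complex", "medium", "simple", "random"])
    def test_energy_and_ledger(self, cx, params):
        rng = np.random.default_rng(42)
        for trial in range(60):
            st = MetabolismState(G_int=rng.uniform(0, 10),
                                 P_int=(rng.uniform(0, 10)
                                        if cx == "complex" else 0.0),
                                 E=rng.uniform(-2, 2),
                                 m=rng.uniform(1500, 4500), m_crit=2400.0)
            x_pr = int(rng.integers(2))
            v = st.m / params["CELL_DENSITY"]
            G_ext, O_ext = nutrient_availability(
                rng.uniform(0, 0.005), rng.uniform(0, 100), 6781.0, 1.3e-6)
            e_cons, e_req = energy_demand(v, x_pr, 0, st.E, params)
            up = glucose_uptake(cx, st, params, G_ext, v, 6781.0, rng)
            g_req, _, o_up0 = nutrient_requirements(cx, params, e_req,
                                                    O_ext, rng)
            g_equiv0 = st.G_int + st.P_int / S_PG
            exp = oracle_energy(cx, st.G_int, st.P_int, g_req, o_up0,
                                st.E, e_cons)
            e_gen, o_up = generate_energy(cx, st, g_req, o_up0, e_cons)
            e_ox, e_gl = exp[0], exp[1]
            assert e_gen == pytest.approx(e_ox + e_gl, abs=1e-12)
            assert st.G_int == pytest.approx(exp[2], abs=1e-12)
            assert st.P_int == pytest.approx(exp[3], abs=1e-12)
            assert o_up == pytest.approx(exp[4], abs=1e-12)
            # carbon spent on ATP: oxphos always burns carbon; glycolysis
            # burns it for the implicit variants but moves it into the
            # pyruvate pool for complex metabolism
            energy_carbon = e_ox / (S_OXPHOS * S_PG)
            if cx != "complex":
                energy_carbon += e_gl / S_GLYC
            update_energy(st, e_gen, e_cons)
            m0 = st.m
            generate_mass(cx, st, params, x_pr, rng)
            dm_gen = st.m - m0
            m1 = st.m
            consume_mass(cx, st, params, x_pr)
            dm_auto = m1 - st.m
            p0 = st.P_int
            finalize_tick(cx, st, params, up, o_up, G_ext, O_ext)
            lactate = p0 - st.P_int
            phi = params["MASS_TO_GLUC"]
            g_equiv1 = st.G_int + st.P_int / S_PG
            balance = (g_equiv0 + dm_auto * phi
                       - dm_gen * phi - lactate / S_PG
                       - energy_carbon - g_equiv1)
            assert balance == pytest.approx(0.0, abs=1e-9), (cx, trial)


class TestPipeline:
    def test_step_metabolism_returns_depletion_factors(self, params):
        st = fresh_state(m=2400.0)
        v, gf, of = step_metabolism("complex", st, params, 0.005, 100.0,
                                    6781.0, 1.3e-6, 1, 0,
                                    np.random.default_rng(0))
        assert v == pytest.approx(st.m / params["CELL_DENSITY"])
        assert 0.0 <= gf <= 1.0 and 0.0 <= of <= 1.0

    def test_ample_nutrients_no_deficit(self, params):
        st = fresh_state(m=2400.0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            step_metabolism("complex", st, params, 0.005, 100.0, 6781.0,
                            1.3e-6, 1, 0, rng)
        assert st.E >= 0.0

    def test_random_metabolism_runs_deficits(self, params):
        st = fresh_state(m=2400.0)
        rng = np.random.default_rng(0)
        deficits = 0
        for _ in range(300):
            step_metabolism("random", st, params, 0.005, 100.0, 6781.0,
                            1.3e-6, 1, 0, rng)
            deficits += st.E < 0
        assert deficits > 150
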