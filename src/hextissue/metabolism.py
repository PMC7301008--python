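"""Intracellular metabolism at four complexity levels.

Each tick (1 min) a cell converts local glucose and oxygen into ATP and
new cell mass through glycolysis and oxidative phosphorylation, with a
metabolic preference μ for glycolysis (the Warburg-effect dial).  Four
module variants trade mechanistic detail for speed:

* ``complex`` — explicit pyruvate intermediate; glucose uptake scales
  with cell surface area (a proxy for receptor count); autophagy
  regulates size.
* ``medium`` — implicit pyruvate; uptake scales with cell volume;
  autophagy retained.
* ``simple`` — constant target ATP production, constant growth rate.
* ``random`` — random fractions of the available nutrients, no
  size regulation; a null-like control that generally fails to meet
  energetic demand.

Stoichiometry: 2 ATP/glucose (glycolysis), 15 ATP/pyruvate (oxphos),
2 pyruvate/glucose, 3 O₂/pyruvate — hence at most 32 ATP per fully
oxidized glucose.

The per-tick pipeline runs in a fixed order: availability → energy
demand → glucose uptake → nutrient requirements → energy generation →
energy update → mass generation → autophagy → cell/environment update.
Amounts are fmol, energy is fmol ATP, mass is pg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import STOICHIOMETRY

S_GLYC = STOICHIOMETRY["S_GLYC"]
S_OXPHOS = STOICHIOMETRY["S_OXPHOS"]
S_PG = STOICHIOMETRY["S_PG"]
S_OP = STOICHIOMETRY["S_OP"]

COMPLEXITIES = ("complex", "medium", "simple", "random")


@dataclass(slots=True)
class MetabolismState:
    """Bookkeeping for one cell's metabolism.

    G_int/P_int are internal glucose/pyruvate pools (fmol), E the energy
    balance (fmol ATP; may run negative as a deficit), m the cell mass
    (pg) and m_crit the mass the cell aims to maintain (doubling to
    2·m_crit enables division).
    """
    G_int: float = 0.0
    P_int: float = 0.0
    E: float = 0.0
    m: float = 0.0
    m_crit: float = 0.0

    def split(self, fraction: float) -> "MetabolismState":
        """Divide module contents at cytokinesis; returns the daughter share."""
        d = MetabolismState(self.G_int * fraction, self.P_int * fraction,
                            self.E * fraction, self.m * fraction, self.m_crit)
        self.G_int *= 1.0 - fraction
        self.P_int *= 1.0 - fraction
        self.E *= 1.0 - fraction
        self.m *= 1.0 - fraction
        return d


def cell_surface_area(v: float, max_height: float) -> float:
    """Surface area of a cylindrical cell of volume v and height MAX_HEIGHT/2."""
    h = max_height / 2.0
    r = math.sqrt(v / (math.pi * h))
    return 2.0 * math.pi * r * h + 2.0 * math.pi * r * r


def nutrient_availability(G_conc, O_conc, hex_volume, oxy_solubility):
    """Available amounts (fmol) from local mean concentrations."""
    return G_conc * hex_volume, O_conc * hex_volume * oxy_solubility


def energy_demand(v, x_pr, x_mi, E_prev, params):
    """(E_cons, E_req): consumption this tick plus carried-over deficit."""
    E_cons = v * (params["BASAL_ENERGY"]
                  + params["PROLIF_ENERGY"] * x_pr
                  + params["MIGRA_ENERGY"] * x_mi)
    E_req = E_cons + max(0.0, -E_prev)
    return E_cons, E_req


def glucose_uptake(complexity, state, params, G_ext, v, hex_volume, rng):
    """Glucose uptake per module variant, clamped to [0, G_ext]."""
    if complexity == "random":
        up = G_ext * rng.uniform(0.005, 0.015)
    elif complexity == "simple":
        up = params["CONS_GLUC_UPTAKE"] * (G_ext / hex_volume - state.G_int / v)
    elif complexity == "medium":
        s_avg = (params["META_PREF"] * S_GLYC
                 + (1.0 - params["META_PREF"]) * S_OXPHOS * S_PG)
        up = (params["ATP_PRODUCTION_RATE"] * v
              * (G_ext / hex_volume - state.G_int / v) / s_avg)
    elif complexity == "complex":
        A = cell_surface_area(v, params["MAX_HEIGHT"])
        up = (params["GLUC_UPTAKE_RATE"] * A
              * (G_ext / hex_volume - state.G_int / v))
    else:
        raise ValueError(f"unknown metabolism complexity {complexity!r}")
    up = min(max(up, 0.0), G_ext)
    state.G_int += up
    return up


def nutrient_requirements(complexity, params, E_req, O_ext, rng):
    """(G_req_glyc, G_req_oxphos_or_P_req, O_uptake) per module variant.

    For complex metabolism the second element is the pyruvate
    requirement; for the others it is the glucose-for-oxphos requirement.
    A non-positive energy requirement yields zero requirements.
    """
    mu = params["META_PREF"]
    if complexity == "random":
        g_glyc = rng.uniform(0.2, 0.4)
        o_up = O_ext * rng.uniform(0.2, 0.5)
        return g_glyc, 0.0, o_up
    if E_req <= 0.0:
        E_req = 0.0
    if complexity == "simple":
        alpha = params["CONS_ATP_PRODUCTION"]
        g_glyc = mu * alpha / S_GLYC
        g_ox = (1.0 - mu) * alpha / (S_OXPHOS * S_PG)
        o_up = min(O_ext, g_ox * S_PG * S_OP)
        return g_glyc, g_ox, o_up
    if complexity == "medium":
        g_glyc = mu * E_req / S_GLYC
        g_ox = (1.0 - mu) * E_req / (S_OXPHOS * S_PG)
        o_up = min(O_ext, g_ox * S_PG * S_OP)
        return g_glyc, g_ox, o_up
    if complexity == "complex":
        g_req = mu * E_req / S_GLYC
        p_req = (1.0 - mu) * E_req / S_OXPHOS
        o_up = min(O_ext, p_req * S_OP)
        return g_req, p_req, o_up
    raise ValueError(f"unknown metabolism complexity {complexity!r}")


def generate_energy(complexity, state, g_req, o_uptake, E_cons):
    """Run oxphos then glycolysis; returns (E_gen, corrected O_uptake).

    Between the two pathways, complex and medium metabolism divert extra
    glucose through glycolysis when oxygen-limited oxphos would leave the
    cell in deficit (hypoxic compensation).
    """
    E_prev = state.E
    # --- oxidative phosphorylation -----------------------------------
    if complexity == "complex":
        p_o = o_uptake / S_OP
        if state.P_int > p_o:
            e_ox = p_o * S_OXPHOS
            state.P_int -= p_o
        else:
            e_ox = state.P_int * S_OXPHOS
            o_uptake = state.P_int * S_OP
            state.P_int = 0.0
    else:
        g_o = o_uptake / (S_PG * S_OP)
        if state.G_int > g_o:
            e_ox = g_o * S_OXPHOS * S_PG
            state.G_int -= g_o
        else:
            e_ox = state.G_int * S_OXPHOS * S_PG
            o_uptake = state.G_int * S_PG * S_OP
            state.G_int = 0.0
    # --- hypoxic glycolysis compensation ------------------------------
    if complexity in ("complex", "medium"):
        g_req = max(g_req, -(E_prev - E_cons + e_ox) / S_GLYC)
        g_req = max(g_req, 0.0)
    # --- glycolysis ----------------------------------------------------
    if complexity == "complex":
        if state.G_int > g_req:
            e_gl = g_req * S_GLYC
            state.G_int -= g_req
            state.P_int += g_req * S_PG
        else:
            e_gl = state.G_int * S_GLYC
            state.P_int += state.G_int * S_PG
            state.G_int = 0.0
    else:
        if state.G_int > g_req:
            e_gl = g_req * S_GLYC
            state.G_int -= g_req
        else:
            e_gl = state.G_int * S_GLYC
            state.G_int = 0.0
    return e_ox + e_gl, o_uptake


def update_energy(state, E_gen, E_cons):
    state.E = state.E + E_gen - E_cons
    # the requirement-driven pathways balance supply against demand
    # exactly; snap round-off residues so they are not read as deficits
    if abs(state.E) < 1e-9:
        state.E = 0.0


def generate_mass(complexity, state, params, x_pr, rng):
    """Build cell mass from the internal pools; only when E >= 0."""
    if state.E < 0.0:
        return 0.0
    phi = params["MASS_TO_GLUC"]
    m, m_crit = state.m, state.m_crit
    grow_for_division = x_pr == 1 and m < 2.0 * m_crit
    maintain = m < 0.99 * m_crit
    dm = 0.0
    if complexity == "random":
        if grow_for_division:
            x_u = rng.uniform(0.0, 1.0)
            dm = x_u * state.G_int / phi
            state.G_int -= x_u * state.G_int
    elif complexity == "simple":
        k_m, rho = params["CONS_GROWTH_RATE"], params["CELL_DENSITY"]
        if grow_for_division and state.G_int > k_m * rho * phi:
            dm = k_m * rho
            state.G_int -= k_m * rho * phi
    elif complexity == "medium":
        if grow_for_division or maintain:
            f_m = params["FRAC_MASS"]
            dm = f_m * state.G_int / phi
            state.G_int *= 1.0 - f_m
    elif complexity == "complex":
        if grow_for_division or maintain:
            f_m, lam = params["FRAC_MASS"], params["RATIO_GLUC_TO_PYRU"]
            dm = f_m * (lam * state.G_int / phi
                        + (1.0 - lam) * state.P_int / (S_PG * phi))
            state.G_int *= 1.0 - f_m * lam
            state.P_int *= 1.0 - f_m * (1.0 - lam)
    else:
        raise ValueError(f"unknown metabolism complexity {complexity!r}")
    state.m += dm
    return dm


def consume_mass(complexity, state, params, x_pr):
    """Autophagy for complex/medium metabolism.

    Triggered under an energy deficit (down to the minimum viable mass)
    or, for non-proliferating cells, to trim mass back toward m_crit.
    """
    if complexity not in ("complex", "medium"):
        return 0.0
    m_min = params["MIN_MASS_FRAC"] * state.m_crit
    starving = state.E < 0.0 and state.m > m_min
    trimming = (state.E >= 0.0 and state.m > 1.01 * state.m_crit and x_pr == 0)
    if not (starving or trimming):
        return 0.0
    k_a = params["AUTOPHAGY_RATE"]
    state.m -= k_a
    state.G_int += k_a * params["MASS_TO_GLUC"]
    return k_a


def finalize_tick(complexity, state, params, g_uptake, o_uptake, G_ext, O_ext):
    """Volume update, lactate loss, and environment depletion factors.

    Returns (volume, glucose factor, oxygen factor); the engine scales
    the cell's six triangles by the factors.
    """
    v = state.m / params["CELL_DENSITY"]
    if complexity == "complex":
        state.P_int *= 1.0 - params["LACTATE_RATE"]
    g_factor = 1.0 - g_uptake / G_ext if G_ext > 0.0 else 1.0
    o_factor = 1.0 - o_uptake / O_ext if O_ext > 0.0 else 1.0
    return v, max(g_factor, 0.0), max(o_factor, 0.0)


def step_metabolism(complexity, state, params, G_conc, O_conc, hex_volume,
                    oxy_solubility, x_pr, x_mi, rng):
    """Run the full per-tick metabolism pipeline for one cell.

    Returns (volume, glucose factor, oxygen factor) for the engine to
    apply to the local environment.
    """
    v = state.m / params["CELL_DENSITY"]
    G_ext, O_ext = nutrient_availability(G_conc, O_conc, hex_volume,
                                         oxy_solubility)
    E_cons, E_req = energy_demand(v, x_pr, x_mi, state.E, params)
    g_up = glucose_uptake(complexity, state, params, G_ext, v, hex_volume, rng)
    # the second element (oxphos glucose / pyruvate requirement) enters
    # only through the oxygen uptake; oxphos itself is oxygen-limited
    g_req, _, o_up = nutrient_requirements(complexity, params, E_req,
                                           O_ext, rng)
    E_gen, o_up = generate_energy(complexity, state, g_req, o_up, E_cons)
    update_energy(state, E_gen, E_cons)
    generate_mass(complexity, state, params, x_pr, rng)
    consume_mass(complexity, state, params, x_pr)
    return finalize_tick(complexity, state, params, g_up, o_up, G_ext, O_ext)
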