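"""Packaged default parameters for the tissue-cell simulator.

All quantities use a single unit system:

* lengths in micrometers (μm), volumes in μm³
* time in minutes for agent rules, seconds for diffusion/ODE sub-steps
* amounts in fmol (glucose, oxygen, pyruvate, ATP)
* bulk concentrations in fmol/μm³ (glucose), mmHg (oxygen partial
  pressure; converted through tissue solubility) and nM (TGFα, all
  intracellular signaling species)
* cell mass in pg, density in pg/μm³

Defaults are drawn from the physiology literature where a standard value
exists (diffusivities, solubility, cell size/density, stoichiometry) and
otherwise calibrated once so the default colony simulation reproduces the
canonical growth benchmarks for epithelial-like tumor cells (exponential
early growth, ~30-35 h population doubling, 16-24 h cell cycle, linear
diameter growth near 1.5 μm/h).  See docs/methods.md for the provenance
of every value.
"""

from __future__ import annotations

import copy

# ---------------------------------------------------------------------------
# environment geometry and lattice parameters
# ---------------------------------------------------------------------------

ENVIRONMENT_DEFAULTS: dict = {
    # hexagon side-to-side width; lattice spacing is half of this
    "HEX_SIZE": 30.0,            # μm
    "MAX_HEIGHT": 8.7,           # μm, one cell layer; also the layer spacing Δz
    # absolute packing ceiling of a location: two cell heights.  The
    # per-agent crowding tolerance (MAX_HEIGHT in the cell parameters)
    # is the binding constraint for unmodified cells.
    "SLAB_HEIGHT": 17.4,         # μm
    # molecule lattice parameters
    "DIFF_GLUC": 110.0,          # μm²/s, glucose in tissue
    "DIFF_OXY": 2000.0,          # μm²/s, oxygen in tissue
    "DIFF_TGF": 51.0,            # μm²/s, ~17 kDa protein in tissue
    "CONC_GLUC": 0.005,          # fmol/μm³ (= 5 mM)
    "CONC_OXY": 100.0,           # mmHg
    "CONC_TGF": 0.05,            # nM far-field extracellular TGFα
    "OXY_SOLU_TISSUE": 1.3e-6,   # fmol O₂ per μm³ per mmHg
    "DIFFUSION_DT": 1.0,         # s, diffusion/ODE sub-step
    "SUBSTEPS_PER_TICK": 60,     # 1-min tick = 60 one-second sub-steps
}

# ---------------------------------------------------------------------------
# tissue-cell agent parameters
# ---------------------------------------------------------------------------

CELL_DEFAULTS: dict = {
    "CELL_VOL_AVG": 2250.0,      # μm³ initial volume mean
    "CELL_VOL_RANGE": 200.0,     # μm³ initial volume s.d.
    "CELL_DENSITY": 1.07,        # pg/μm³
    "DEATH_AGE_AVG": 120960.0,   # min (12 weeks)
    "DEATH_AGE_RANGE": 10080.0,  # min (1 week)
    "DIVISION_POTENTIAL": 50.0,  # divisions before senescence check
    "SYNTHESIS_TIME": 637.0,     # min of S phase required before division
    "MIGRA_RATE": 0.05,          # μm/min; migration delay = HEX_SIZE / rate (600 min)
    "MIGRA_THRESHOLD": 1.0001,   # PLCγ fold-change θ above which cells migrate
    "MAX_HEIGHT": 8.7,           # μm crowding tolerance
    "META_PREF": 0.3,            # μ, glycolytic preference
    "ENERGY_THRESHOLD": 720.0,   # min of sustained deficit before necrosis
    "NECRO_FRAC": 0.5,           # P(apoptosis instead of necrosis)
    "SENES_FRAC": 0.5,           # P(senescence instead of apoptosis) at limit
    "DEATH_TIME": 1440.0,        # min from apoptosis commitment to removal
    "AFFINITY": 0.11,            # α in the migration score
    "ACCURACY": 0.5,             # β in the migration score
    "HETEROGENEITY": 0.0,        # % of default value used as trunc-normal s.d.
    "MIGRA_PROB": 0.25,          # random-signaling migration probability
    "MIN_MASS_FRAC": 0.5,        # m_min = MIN_MASS_FRAC · m_crit
}

#: parameters the heterogeneity mechanism perturbs at division
HETEROGENEOUS_PARAMS: tuple = ("MAX_HEIGHT", "META_PREF", "MIGRA_THRESHOLD")

#: physical bounds used when truncating heterogeneous draws
PARAM_BOUNDS: dict = {
    "MAX_HEIGHT": (1e-3, 17.4),
    "META_PREF": (0.0, 1.0),
    "MIGRA_THRESHOLD": (1.0, float("inf")),
}

# ---------------------------------------------------------------------------
# metabolism module parameters
# ---------------------------------------------------------------------------

METABOLISM_DEFAULTS: dict = {
    "BASAL_ENERGY": 0.00075,      # fmol ATP / μm³ / min
    "PROLIF_ENERGY": 0.00075,     # extra fmol ATP / μm³ / min while proliferative
    "MIGRA_ENERGY": 0.0004,       # extra fmol ATP / μm³ / min while migratory
    "CONS_GLUC_UPTAKE": 2.0e5,    # k_U, μm³/min (simple)
    "ATP_PRODUCTION_RATE": 6.5,   # k_P, fmol ATP / μm³-conc / min (medium)
    "GLUC_UPTAKE_RATE": 0.7,      # k_G, μm/min per unit conc (complex, x area)
    "CONS_ATP_PRODUCTION": 4.5,   # α, fmol ATP/min constant target (simple)
    "FRAC_MASS": 0.0195,          # f_m, fraction of pools turned to mass per min
    "MASS_TO_GLUC": 0.1,          # φ, fmol glucose per pg mass
    "CONS_GROWTH_RATE": 1.9,      # k_M, μm³/min constant growth (simple)
    "RATIO_GLUC_TO_PYRU": 0.8,    # λ_m
    "AUTOPHAGY_RATE": 1.0,        # k_A, pg/min
    "LACTATE_RATE": 0.1,          # k_L, fraction of pyruvate lost per min
}

#: fixed stoichiometric constants (ATP/glucose, ATP/pyruvate, ...)
STOICHIOMETRY: dict = {
    "S_GLYC": 2.0,      # ATP per glucose through glycolysis
    "S_OXPHOS": 15.0,   # ATP per pyruvate through oxidative phosphorylation
    "S_PG": 2.0,        # pyruvate per glucose
    "S_OP": 3.0,        # oxygen per pyruvate
}

# ---------------------------------------------------------------------------
# signaling module parameters
# ---------------------------------------------------------------------------
# Rate constants are per second (forward Euler with 1 s steps); binding
# rates are per nM per second.  Index meaning follows the per-complexity
# ODE systems in the signaling module.

SIGNALING_DEFAULTS: dict = {
    "simple": {
        "k1": 2.0e-3,   # TGFα uptake/complex formation (nM⁻¹... wired as 1st order)
        "k2": 2.0e-3,   # cytoplasmic complex degradation
        "k3": 1.0e-3,   # extracellular TGFα decay
        "k4": 1.5e-3,   # PLCγ activation
        "k5": 1.5e-3,   # PLCγ deactivation
        "k6": 3.0e-4,   # TGFα secretion (constant)
    },
    "medium": {
        "k1": 1.0e-3, "k-1": 2.0e-3,
        "k2": 5.0e-3, "k-2": 5.0e-3,
        "k3": 1.0e-3, "k4": 1.5e-3, "k5": 2.0e-3,
        "k6": 5.0e-4, "k7": 5.0e-4,
        "k8": 1.5e-3, "k9": 1.5e-3,
        "k10": 1.2e-2, "k11": 1.0e-4,
    },
    "complex": {
        "k1": 1.0e-3, "k-1": 2.0e-3,
        "k2": 5.0e-3, "k-2": 5.0e-3,
        "k3": 1.0e-3, "k4": 1.5e-3,
        "k5": 1.0e-2, "k-5": 1.0e-3,
        "k6": 5.0e-4, "k7": 2.0e-3,
        "k8": 2.0e-3, "k-8": 1.0e-3,
        "k9": 1.5e-3, "k10": 5.0e-4, "k11": 2.0e-3,
        "k12": 1.5e-3, "k13": 1.5e-3,
        "k14": 2.0e-3, "k15": 2.0e-3,
        "k16": 1.0e-3, "k17": 1.0e-3,
        "k18": 5.0e-4, "k19": 5.0e-4,
    },
    # half-saturation constants of the regulatory weights
    "W_G": 0.005,   # fmol/μm³, internal glucose concentration scale
    "W_C": 0.5,     # nM
    "W_P": 20.0,    # nM
    "W_E": 0.5,     # nM
    "W_T": 0.5,     # nM
}

VALID_COMPLEXITIES = ("complex", "medium", "simple", "random")


def default_cell_params() -> dict:
    merged = dict(CELL_DEFAULTS)
    merged.update(METABOLISM_DEFAULTS)
    return merged


def default_environment_params() -> dict:
    return dict(ENVIRONMENT_DEFAULTS)


def default_signaling_params() -> dict:
    return copy.deepcopy(SIGNALING_DEFAULTS)


#: every recognised parameter name, used for scenario validation
VALID_CELL_PARAMS = frozenset(default_cell_params())
VALID_ENV_PARAMS = frozenset(ENVIRONMENT_DEFAULTS)
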