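"""Tissue-cell agents: the seven-state rule engine and helper agents.

Each cell agent is in exactly one of seven states — apoptotic, necrotic,
quiescent, migratory, proliferative, senescent, undecided — and at every
tick steps through: aging and the age-dependent apoptosis check, the
metabolism module, starvation/energy checks, the signaling module and
the migrate-vs-proliferate decision, and the replicative-senescence
check.

Time-delayed actions (migration, division, apoptotic removal, insertion
of new populations) are implemented as helper agents scheduled by the
engine.  Necrotic cells stay in the grid but are never stepped again;
apoptotic cells are removed from both grid and schedule when their
removal helper fires, triggering compensatory proliferation of one
quiescent neighbor.

Population heterogeneity: daughters draw selected parameters from
truncated normal distributions centered on the parent's values with a
standard deviation of H percent of the population default, which lets
clonal lineages drift toward fitter parameter values.
"""

from __future__ import annotations

import math

from .config import HETEROGENEOUS_PARAMS, PARAM_BOUNDS
from .metabolism import MetabolismState, step_metabolism
from .signaling import (SignalingState, decide_random, decide_state)

# cell states
APOPTOTIC = "apoptotic"
NECROTIC = "necrotic"
QUIESCENT = "quiescent"
MIGRATORY = "migratory"
PROLIFERATIVE = "proliferative"
SENESCENT = "senescent"
UNDECIDED = "undecided"

ALL_STATES = (APOPTOTIC, NECROTIC, QUIESCENT, MIGRATORY, PROLIFERATIVE,
              SENESCENT, UNDECIDED)
#: absorbing states of the null model
TERMINAL_STATES = (APOPTOTIC, NECROTIC, SENESCENT)
#: states an energy deficit pushes into quiescence
ACTIVE_STATES = (MIGRATORY, PROLIFERATIVE, UNDECIDED)

#: quiescent cells re-test the contact-inhibition constraint at this
#: interval (ticks); a compromise between responsiveness and cost
QUIESCENCE_RECHECK = 30


class CellAgent:
    """One tissue cell on the hexagonal grid."""

    __slots__ = ("cid", "label", "cell_class", "state", "params", "loc",
                 "age", "division_count", "x_mi", "x_pr", "metab", "signal",
                 "metab_complexity", "sig_complexity", "deficit_ticks",
                 "cycle_start", "cycle_lengths", "synth_ticks", "null_model",
                 "can_exit_quiescence", "removed", "fixed")

    def __init__(self, cid, label, cell_class, params, loc,
                 metab_complexity, sig_complexity, signaling_params,
                 conc_tgfa, rng, null_model=False, can_exit_quiescence=True,
                 volume=None, age=None):
        self.cid = cid
        self.label = label
        self.cell_class = cell_class
        self.params = params
        self.loc = loc
        self.state = UNDECIDED
        self.x_mi = 0
        self.x_pr = 0
        self.division_count = 0
        self.deficit_ticks = 0
        self.cycle_start = -1
        self.cycle_lengths = []
        self.synth_ticks = 0
        self.null_model = null_model
        self.can_exit_quiescence = can_exit_quiescence
        self.removed = False
        self.fixed = False
        self.metab_complexity = metab_complexity
        self.sig_complexity = sig_complexity
        if volume is None:
            volume = -1.0
            while volume <= 0.0:
                volume = rng.normal(params["CELL_VOL_AVG"],
                                    params["CELL_VOL_RANGE"])
        if age is None:
            age = rng.uniform(0.0, params["DEATH_AGE_RANGE"])
        self.age = float(age)
        m = volume * params["CELL_DENSITY"]
        self.metab = MetabolismState(G_int=0.0, P_int=0.0, E=0.0, m=m,
                                     m_crit=m)
        if sig_complexity in ("random", "none"):
            self.signal = None
        else:
            self.signal = SignalingState(sig_complexity, signaling_params,
                                         conc_tgfa)

    @property
    def volume(self) -> float:
        return self.metab.m / self.params["CELL_DENSITY"]

    @property
    def is_scheduled(self) -> bool:
        return not self.removed and self.state != NECROTIC

    def clear_flags(self):
        self.x_mi = 0
        self.x_pr = 0


# ---------------------------------------------------------------------------
# probabilistic sub-rules
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)


def apoptosis_by_age(age, death_age_avg, death_age_range, rng) -> bool:
    """Age-dependent apoptosis: P = Φ((age - avg)/range), sampled per tick."""
    z = (age - death_age_avg) / death_age_range
    if z < -7.0:       # probability < 1e-12: skip the draw
        return False
    p = 0.5 * (1.0 + math.erf(z / _SQRT2))
    return rng.uniform() < p


def draw_heterogeneous_params(parent_params, heterogeneity, defaults, rng):
    """Daughter parameter set under H% heterogeneity.

    Each heterogeneity-enabled parameter is drawn from a normal
    distribution with mean = parent value and s.d. = H% of the *default*
    value, truncated (by resampling, then clipping) to physical bounds.
    """
    child = dict(parent_params)
    if heterogeneity <= 0.0:
        return child
    for name in HETEROGENEOUS_PARAMS:
        sd = heterogeneity / 100.0 * defaults[name]
        lo, hi = PARAM_BOUNDS[name]
        val = rng.normal(parent_params[name], sd)
        tries = 0
        while not (lo <= val <= hi) and tries < 100:
            val = rng.normal(parent_params[name], sd)
            tries += 1
        child[name] = min(max(val, lo), hi)
    return child


# ---------------------------------------------------------------------------
# location constraints and scoring
# ---------------------------------------------------------------------------

def location_admits(sim, loc, cell, added_volume, exclude_self=True) -> bool:
    """Check whether a location can accept ``cell`` (or its daughter).

    Criteria: (i) total volume within the location capacity, (ii) every
    occupant's height within its own crowding tolerance after addition,
    (iii) at most six agents, and (iv) at most one healthy-class (H)
    agent per location.  ``exclude_self`` discounts the cell's own
    presence (migration: the cell vacates its old location); for
    division the parent stays and must be counted.
    """
    geom = sim.geom
    occupants = sim.grid.get(loc, ())
    others = ([c for c in occupants if c is not cell] if exclude_self
              else list(occupants))
    if len(others) + 1 > 6:
        return False
    if cell.cell_class == "H" and any(c.cell_class == "H" for c in others):
        return False
    total = sum(c.volume for c in others) + added_volume
    if total > geom.location_capacity:
        return False
    height = total / geom.hex_area
    if height > cell.params["MAX_HEIGHT"]:
        return False
    for c in others:
        if height > c.params["MAX_HEIGHT"]:
            return False
    return True


def find_valid_locations(sim, cell, added_volume=None, exclude_self=None):
    """Current location plus neighbors that can accept the cell/daughter.

    With no ``added_volume`` the query is for the migrating cell itself
    (self excluded from occupancy); otherwise it is for a daughter of
    that volume with the parent staying put.
    """
    if exclude_self is None:
        exclude_self = added_volume is None
    if added_volume is None:
        added_volume = cell.volume
    u, v, w, z = cell.loc
    candidates = [cell.loc] + sim.geom.neighbors(u, v, w, z)
    return [loc for loc in candidates
            if location_admits(sim, loc, cell, added_volume, exclude_self)]


def score_location(sim, loc, rng) -> float:
    """Chemotactic migration/division score of a candidate location.

    S = α (R - r_i + 1)/2 + (1-α) [β G_i/G° + (1-β) u] with α the
    affinity for the environment center, β the chemotactic accuracy,
    G_i the local glucose concentration, G° the source concentration
    and u ~ U(0, 1).
    """
    p = sim.default_cell_params
    alpha, beta = p["AFFINITY"], p["ACCURACY"]
    r_i = (abs(loc[0]) + abs(loc[1]) + abs(loc[2])) // 2
    g = sim.fields["glucose"].mean_at_hex(*loc)
    g0 = sim.env_params["CONC_GLUC"]
    u = rng.uniform()
    return (alpha * (sim.geom.R - r_i + 1) / 2.0
            + (1.0 - alpha) * (beta * g / g0 + (1.0 - beta) * u))


def best_location(sim, locations, rng):
    """Argmax of the location score; seeded-uniform among exact ties."""
    scores = [score_location(sim, loc, rng) for loc in locations]
    top = max(scores)
    ties = [loc for loc, s in zip(locations, scores) if s == top]
    if len(ties) == 1:
        return ties[0]
    return ties[int(rng.integers(len(ties)))]


# ---------------------------------------------------------------------------
# state transitions
# ---------------------------------------------------------------------------

def become_apoptotic(sim, cell):
    cell.state = APOPTOTIC
    cell.clear_flags()
    sim.add_helper(ApoptoseHelper(cell, sim.tick + cell.params["DEATH_TIME"]))


def become_necrotic_or_apoptotic(sim, cell, rng):
    """Sustained starvation: necrosis, or apoptosis with P = NECRO_FRAC."""
    if rng.uniform() < cell.params["NECRO_FRAC"]:
        become_apoptotic(sim, cell)
    else:
        cell.state = NECROTIC
        cell.clear_flags()
        sim.unschedule(cell)


def commit_decision(sim, cell, x_mi, x_pr):
    cell.x_mi, cell.x_pr = x_mi, x_pr
    if x_mi:
        cell.state = MIGRATORY
        delay = sim.geom.hex_size / cell.params["MIGRA_RATE"]
        sim.add_helper(MigrateHelper(cell, sim.tick + delay))
    else:
        cell.state = PROLIFERATIVE
        # cycle length is tracked from the (latest) switch into the
        # proliferative state until the completed division
        cell.cycle_start = sim.tick
        sim.add_helper(ProliferateHelper(cell, sim.tick))


# ---------------------------------------------------------------------------
# per-tick rule
# ---------------------------------------------------------------------------

def _run_metabolism(sim, cell, rng):
    u, v, w, z = cell.loc
    gluc, oxy = sim.fields["glucose"], sim.fields["oxygen"]
    g_conc = gluc.mean_at_hex(u, v, w, z)
    o_conc = oxy.mean_at_hex(u, v, w, z)
    _, g_factor, o_factor = step_metabolism(
        cell.metab_complexity, cell.metab, cell.params, g_conc, o_conc,
        sim.geom.hex_volume, sim.env_params["OXY_SOLU_TISSUE"],
        cell.x_pr, cell.x_mi, rng)
    if g_factor < 1.0:
        gluc.scale_at_hex(g_factor, u, v, w, z)
    if o_factor < 1.0:
        oxy.scale_at_hex(o_factor, u, v, w, z)


def _run_signaling(sim, cell):
    """Integrate the mechanistic signaling network; returns Δ or None."""
    if cell.signal is None:
        return None
    u, v, w, z = cell.loc
    tgfa = sim.fields["tgfa"]
    t_local = tgfa.mean_at_hex(u, v, w, z)
    g_int_conc = cell.metab.G_int / max(cell.volume, 1e-12)
    t_new, delta = cell.signal.integrate_tick(
        t_local, g_int_conc,
        dt=sim.env_params["DIFFUSION_DT"],
        substeps=sim.env_params["SUBSTEPS_PER_TICK"])
    tgfa.set_at_hex(t_new, u, v, w, z)
    return delta


def step_cell(sim, cell, rng):
    """Advance one cell by one tick (1 min)."""
    if cell.removed or cell.state in (NECROTIC, APOPTOTIC):
        return
    p = cell.params

    # fixed-state profiling agents run their modules but follow no rules
    if cell.fixed:
        if cell.metab_complexity != "none":
            _run_metabolism(sim, cell, rng)
        _run_signaling(sim, cell)
        return

    cell.age += 1.0

    # 1. lifespan: senescent cells no longer apoptose from age
    if cell.state != SENESCENT and apoptosis_by_age(
            cell.age, p["DEATH_AGE_AVG"], p["DEATH_AGE_RANGE"], rng):
        become_apoptotic(sim, cell)
        return

    # 2. metabolism
    if cell.metab_complexity != "none":
        _run_metabolism(sim, cell, rng)

        # 3. starvation / energy checks
        if cell.metab.E < 0.0:
            cell.deficit_ticks += 1
            if cell.deficit_ticks > p["ENERGY_THRESHOLD"]:
                become_necrotic_or_apoptotic(sim, cell, rng)
                return
            if cell.state in ACTIVE_STATES:
                cell.state = QUIESCENT
                cell.clear_flags()
        else:
            cell.deficit_ticks = 0

    # 4. signaling and the migrate/proliferate decision
    delta = _run_signaling(sim, cell)
    if cell.null_model:
        _null_transition(sim, cell, rng)
        return
    if cell.state == UNDECIDED:
        if cell.sig_complexity == "random":
            commit_decision(sim, cell, *decide_random(p["MIGRA_PROB"], rng))
        elif delta is not None:
            commit_decision(sim, cell, *decide_state(delta,
                                                     p["MIGRA_THRESHOLD"]))

    # 5. replicative limit
    if (cell.division_count >= p["DIVISION_POTENTIAL"]
            and cell.state in ACTIVE_STATES + (QUIESCENT,)):
        if rng.uniform() < p["SENES_FRAC"]:
            cell.state = SENESCENT
        else:
            become_apoptotic(sim, cell)
        cell.clear_flags()
        return

    # 6. contact-inhibition release: quiescent cells re-enter the cycle
    #    when energy is restored and space is available
    if (cell.state == QUIESCENT and cell.can_exit_quiescence
            and cell.metab.E >= 0.0
            and (cell.cid + sim.tick) % QUIESCENCE_RECHECK == 0
            and find_valid_locations(sim, cell,
                                     added_volume=cell.volume * 0.5)):
        cell.state = UNDECIDED


def _null_transition(sim, cell, rng):
    """Null model: random state each tick, terminal states absorbing."""
    if cell.state in TERMINAL_STATES:
        return
    new = ALL_STATES[int(rng.integers(len(ALL_STATES)))]
    if new == cell.state:
        return
    cell.clear_flags()
    if new == APOPTOTIC:
        become_apoptotic(sim, cell)
    elif new == NECROTIC:
        cell.state = NECROTIC
        sim.unschedule(cell)
    elif new == MIGRATORY:
        commit_decision(sim, cell, 1, 0)
    elif new == PROLIFERATIVE:
        commit_decision(sim, cell, 0, 1)
    else:
        cell.state = new


# ---------------------------------------------------------------------------
# helper agents
# ---------------------------------------------------------------------------

class Helper:
    """A scheduled, time-delayed cell action or perturbation."""

    kind = "helper"
    #: helpers with a due tick fire once; per-tick helpers fire each tick
    per_tick = False

    def __init__(self, owner, due):
        self.owner = owner
        self.due = due
        self.done = False

    def step(self, sim, rng):  # pragma: no cover - interface
        raise NotImplementedError


class MigrateHelper(Helper):
    """Completes a migration after the HEX_SIZE / MIGRA_RATE delay."""

    kind = "migrate"

    def step(self, sim, rng):
        self.done = True
        cell = self.owner
        if cell.removed or cell.state != MIGRATORY:
            return
        valid = find_valid_locations(sim, cell)
        if not valid:
            cell.state = QUIESCENT
            cell.clear_flags()
            return
        target = best_location(sim, valid, rng)
        if target != cell.loc:
            sim.move_cell(cell, target)
        cell.state = UNDECIDED
        cell.clear_flags()


class ProliferateHelper(Helper):
    """Checked every tick until division completes or aborts.

    S-phase progress (``synth_ticks``) accumulates while the cell is
    proliferative and survives transient interruptions (a brief
    energy-driven quiescent spell does not undo DNA synthesis); it is
    reset only by a completed division.
    """

    kind = "proliferate"
    per_tick = True

    def __init__(self, owner, start_tick):
        super().__init__(owner, start_tick)
        self.start = start_tick

    def step(self, sim, rng):
        cell = self.owner
        if cell.removed or cell.state != PROLIFERATIVE:
            self.done = True
            return
        p = cell.params
        geom = sim.geom
        cell.synth_ticks += 1
        # abort on intolerable height at the current location
        occupants = sim.grid.get(cell.loc, ())
        height = sum(c.volume for c in occupants) / geom.hex_area
        if height > p["MAX_HEIGHT"]:
            cell.state = QUIESCENT
            cell.clear_flags()
            self.done = True
            return
        valid = find_valid_locations(sim, cell,
                                     added_volume=cell.volume * 0.5)
        if not valid:
            cell.state = QUIESCENT
            cell.clear_flags()
            self.done = True
            return
        if (cell.metab.m >= 2.0 * cell.metab.m_crit
                and cell.synth_ticks >= p["SYNTHESIS_TIME"]):
            self._divide(sim, cell, valid, rng)
            self.done = True

    def _divide(self, sim, cell, valid, rng):
        fraction = rng.uniform(0.45, 0.55)
        target = best_location(sim, valid, rng)
        daughter_metab = cell.metab.split(fraction)
        h = cell.params.get("HETEROGENEITY", 0.0)
        child_params = draw_heterogeneous_params(
            cell.params, h, sim.default_cell_params, rng)
        daughter = CellAgent.__new__(CellAgent)
        daughter.cid = sim.next_cell_id()
        daughter.label = cell.label
        daughter.cell_class = cell.cell_class
        daughter.params = child_params
        daughter.loc = target
        daughter.state = UNDECIDED
        daughter.x_mi = daughter.x_pr = 0
        daughter.age = 0.0
        daughter.division_count = cell.division_count + 1
        daughter.deficit_ticks = 0
        daughter.cycle_start = -1
        daughter.cycle_lengths = []
        daughter.synth_ticks = 0
        daughter.null_model = cell.null_model
        daughter.can_exit_quiescence = cell.can_exit_quiescence
        daughter.removed = False
        daughter.fixed = False
        daughter.metab_complexity = cell.metab_complexity
        daughter.sig_complexity = cell.sig_complexity
        daughter.metab = daughter_metab
        daughter.signal = (cell.signal.copy_for_daughter()
                           if cell.signal is not None else None)
        sim.add_cell(daughter)
        cell.division_count += 1
        if cell.cycle_start >= 0:
            cell.cycle_lengths.append(sim.tick - cell.cycle_start)
        cell.cycle_start = -1
        cell.synth_ticks = 0
        cell.state = UNDECIDED
        cell.clear_flags()


class ApoptoseHelper(Helper):
    """Removes an apoptotic cell after DEATH_TIME, with compensatory
    proliferation of one quiescent neighbor."""

    kind = "apoptose"

    def step(self, sim, rng):
        self.done = True
        cell = self.owner
        if cell.removed or cell.state != APOPTOTIC:
            return
        u, v, w, z = cell.loc
        neighbors = sim.geom.neighbors(u, v, w, z)
        quiescent = [c for loc in neighbors
                     for c in sim.grid.get(loc, ())
                     if c.state == QUIESCENT]
        sim.remove_cell(cell)
        if quiescent:
            chosen = quiescent[int(rng.integers(len(quiescent)))]
            chosen.state = PROLIFERATIVE
            chosen.x_mi, chosen.x_pr = 0, 1
            chosen.cycle_start = sim.tick
            sim.add_helper(ProliferateHelper(chosen, sim.tick))


class InsertHelper(Helper):
    """Introduces new cell populations into a center region at a set tick."""

    kind = "insert"

    def __init__(self, due, populations, radius):
        super().__init__(None, due)
        self.populations = populations   # list of (PopulationSpec, weight)
        self.radius = radius

    def step(self, sim, rng):
        self.done = True
        sim.insert_populations(self.populations, self.radius, rng)


class WoundHelper(Helper):
    """Clears all agents in a center disk (environment perturbation)."""

    kind = "wound"

    def __init__(self, due, radius):
        super().__init__(None, due)
        self.radius = radius

    def step(self, sim, rng):
        self.done = True
        for loc in list(sim.grid):
            r = (abs(loc[0]) + abs(loc[1]) + abs(loc[2])) // 2
            if r <= self.radius:
                for cell in list(sim.grid[loc]):
                    sim.remove_cell(cell)
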