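"""Simulation engine: series, scheduler, scenario parsing, snapshots.

A *series* groups replicate simulations that differ only in random seed.
Scenarios are described in XML::

    <scenario>
      <series name="growth" seeds="0..4">
        <simulation radius="16" margin="4" height="1" days="7"
                    interval="720" init="colony"/>
        <agents>
          <population label="X" class="C" count="1"
                      metabolism="complex" signaling="complex">
            <param name="META_PREF" percent="+50"/>
          </population>
        </agents>
        <environment>
          <param name="CONC_GLUC" value="0.005"/>
        </environment>
      </series>
    </scenario>

One tick represents one simulated minute.  Each tick the engine (1)
applies the diffusion sub-steps with constant vasculature sources, (2)
steps every scheduled agent in a freshly shuffled order, (3) fires due
helper agents, and (4) increments the tick.  A simulation consumes a
single seeded RNG stream in that fixed order, so a (scenario, seed)
pair reproduces its output byte for byte.

Output is one JSON file per seed: a header echoing the scenario and the
fully resolved parameter list of every population, then an array of
snapshots with the state of every live agent (necrotic cells included).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cells as C
from .config import (VALID_CELL_PARAMS, VALID_ENV_PARAMS,
                     default_cell_params, default_environment_params,
                     default_signaling_params, VALID_COMPLEXITIES)
from .diffusion import MoleculeField
from .geometry import HexGeometry, hex_disk


class ScenarioError(ValueError):
    """Raised for malformed or inconsistent scenario inputs."""


@dataclass
class PopulationSpec:
    """One cell population within a series."""
    label: str
    cell_class: str = "C"                  # H (healthy), C, or S
    count: int | None = None               # initial number of agents
    fraction: float | None = None          # of seeded agents / of grid
    parameter_overrides: dict = field(default_factory=dict)
    percent_overrides: dict = field(default_factory=dict)
    heterogeneity: float = 0.0             # H, percent
    can_exit_quiescence: bool = True
    metabolism: str = "complex"
    signaling: str = "complex"
    null_model: bool = False
    background: bool = False               # tissue background population
    insert_day: float | None = None        # delayed introduction (days)
    fixed_state: str | None = None         # e.g. "quiescent" profiling agents

    def resolve_params(self, defaults: dict) -> dict:
        p = dict(defaults)
        for name, val in self.parameter_overrides.items():
            if name not in VALID_CELL_PARAMS:
                raise ScenarioError(
                    f"unknown cell parameter {name!r}; valid names: "
                    f"{sorted(VALID_CELL_PARAMS)}")
            p[name] = float(val)
        for name, pct in self.percent_overrides.items():
            if name not in VALID_CELL_PARAMS:
                raise ScenarioError(
                    f"unknown cell parameter {name!r}; valid names: "
                    f"{sorted(VALID_CELL_PARAMS)}")
            p[name] = p[name] * (1.0 + float(pct) / 100.0)
        p["HETEROGENEITY"] = float(self.heterogeneity)
        return p


@dataclass
class SimulationSeries:
    """Scenario for a group of replicate simulations."""
    name: str
    radius: int = 16
    margin: int = 4
    height: int = 1
    days: float = 7.0
    snapshot_interval: int = 720           # minutes
    seeds: list = field(default_factory=lambda: [0])
    populations: list = field(default_factory=list)
    environment: dict = field(default_factory=dict)
    init: str = "colony"                   # colony | tissue
    insert_radius: int = 5                 # hexes, for delayed insertion

    def __post_init__(self):
        if self.radius < 1 or self.margin < 0 or self.height < 1:
            raise ScenarioError("require radius >= 1, margin >= 0, height >= 1")
        if self.days <= 0:
            raise ScenarioError("days must be positive")
        if not self.seeds or len(set(self.seeds)) != len(self.seeds):
            raise ScenarioError("seeds must be non-empty and distinct")
        for name in self.environment:
            if name not in VALID_ENV_PARAMS:
                raise ScenarioError(
                    f"unknown environment parameter {name!r}; valid names: "
                    f"{sorted(VALID_ENV_PARAMS)}")
        for pop in self.populations:
            if pop.metabolism not in VALID_COMPLEXITIES + ("none",):
                raise ScenarioError(f"unknown metabolism {pop.metabolism!r}")
            if pop.signaling not in VALID_COMPLEXITIES + ("none",):
                raise ScenarioError(f"unknown signaling {pop.signaling!r}")

    @property
    def ticks(self) -> int:
        return int(round(self.days * 24 * 60))


# ---------------------------------------------------------------------------
# scenario parsing
# ---------------------------------------------------------------------------

def _parse_seeds(text: str) -> list[int]:
    text = text.strip()
    if ".." in text:
        a, b = text.split("..")
        return list(range(int(a), int(b) + 1))
    return [int(s) for s in text.split(",") if s.strip() != ""]


def _parse_params(elem):
    values, percents = {}, {}
    for p in elem.findall("param"):
        name = p.get("name")
        if name is None:
            raise ScenarioError("param element missing required 'name'")
        if p.get("value") is not None:
            values[name] = float(p.get("value"))
        elif p.get("percent") is not None:
            percents[name] = float(p.get("percent"))
        else:
            raise ScenarioError(f"param {name!r} needs 'value' or 'percent'")
    return values, percents


def parse_scenario(xml_text: str) -> list[SimulationSeries]:
    """Parse a scenario document into simulation series."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise ScenarioError(f"malformed scenario XML: {exc}") from exc
    series_elems = root.findall("series") if root.tag == "scenario" else \
        ([root] if root.tag == "series" else [])
    if not series_elems:
        raise ScenarioError("scenario is missing required tag 'series'")
    out = []
    for se in series_elems:
        sim = se.find("simulation")
        if sim is None:
            raise ScenarioError("series is missing required tag 'simulation'")
        agents = se.find("agents")
        if agents is None:
            raise ScenarioError("series is missing required tag 'agents'")
        pops = []
        for pe in agents.findall("population"):
            values, percents = _parse_params(pe)
            pops.append(PopulationSpec(
                label=pe.get("label", "X"),
                cell_class=pe.get("class", "C"),
                count=int(pe.get("count")) if pe.get("count") else None,
                fraction=(float(pe.get("fraction"))
                          if pe.get("fraction") else None),
                parameter_overrides=values,
                percent_overrides=percents,
                heterogeneity=float(pe.get("heterogeneity", 0.0)),
                can_exit_quiescence=pe.get(
                    "can_exit_quiescence", "true").lower() != "false",
                metabolism=pe.get("metabolism", "complex"),
                signaling=pe.get("signaling", "complex"),
                null_model=pe.get("null", "false").lower() == "true",
                background=pe.get("background", "false").lower() == "true",
                insert_day=(float(pe.get("insert_day"))
                            if pe.get("insert_day") else None),
                fixed_state=pe.get("fixed_state"),
            ))
        env_elem = se.find("environment")
        env = {}
        if env_elem is not None:
            values, percents = _parse_params(env_elem)
            env.update(values)
            base = default_environment_params()
            for name, pct in percents.items():
                if name not in base:
                    raise ScenarioError(
                        f"unknown environment parameter {name!r}; valid "
                        f"names: {sorted(VALID_ENV_PARAMS)}")
                env[name] = base[name] * (1.0 + pct / 100.0)
        seeds = _parse_seeds(se.get("seeds", "0"))
        out.append(SimulationSeries(
            name=se.get("name", "series"),
            radius=int(sim.get("radius", 16)),
            margin=int(sim.get("margin", 4)),
            height=int(sim.get("height", 1)),
            days=float(sim.get("days", 7)),
            snapshot_interval=int(sim.get("interval", 720)),
            seeds=seeds,
            populations=pops,
            environment=env,
            init=sim.get("init", "colony"),
            insert_radius=int(sim.get("insert_radius", 5)),
        ))
    return out


# ---------------------------------------------------------------------------
# simulation instance
# ---------------------------------------------------------------------------

class Simulation:
    """One simulation instance: environment + agents for a single seed."""

    def __init__(self, series: SimulationSeries, seed: int):
        self.series = series
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.tick = 0
        self._cid = 0
        self.env_params = default_environment_params()
        self.env_params.update(series.environment)
        self.default_cell_params = default_cell_params()
        self.signaling_params = default_signaling_params()
        ep = self.env_params
        self.geom = HexGeometry(series.radius, series.margin, series.height,
                                hex_size=ep["HEX_SIZE"],
                                max_height=ep["MAX_HEIGHT"],
                                slab_height=ep["SLAB_HEIGHT"])
        dt = ep["DIFFUSION_DT"]
        self.fields = {
            "glucose": MoleculeField("glucose", self.geom, ep["DIFF_GLUC"],
                                     ep["CONC_GLUC"], ep["CONC_GLUC"], dt),
            "oxygen": MoleculeField("oxygen", self.geom, ep["DIFF_OXY"],
                                    ep["CONC_OXY"], ep["CONC_OXY"], dt),
            # TGFα has no stimulating source: the margin clamp sits at the
            # far-field level (= initial concentration), so the vasculature
            # only clears cell-secreted excess
            "tgfa": MoleculeField("tgfa", self.geom, ep["DIFF_TGF"],
                                  ep["CONC_TGF"], ep["CONC_TGF"], dt),
        }
        self.grid: dict = {}
        self.cells: list = []
        self.helpers: list = []
        self.snapshots: list = []
        self._resolved: dict = {}
        self._pop_by_label: dict = {}
        self._initialize_populations()

    # -- bookkeeping -------------------------------------------------------

    def next_cell_id(self) -> int:
        self._cid += 1
        return self._cid

    def add_cell(self, cell):
        self.cells.append(cell)
        self.grid.setdefault(cell.loc, []).append(cell)

    def remove_cell(self, cell):
        cell.removed = True
        self.grid[cell.loc].remove(cell)
        self.cells.remove(cell)

    def move_cell(self, cell, loc):
        self.grid[cell.loc].remove(cell)
        cell.loc = loc
        self.grid.setdefault(loc, []).append(cell)

    def unschedule(self, cell):
        pass  # scheduling is derived from cell state (necrotic => skipped)

    def add_helper(self, helper):
        self.helpers.append(helper)

    # -- initialization ----------------------------------------------------

    def _make_cell(self, spec: PopulationSpec, loc, rng):
        params = self._resolved[spec.label]
        if spec.heterogeneity > 0.0:
            params = C.draw_heterogeneous_params(
                params, spec.heterogeneity, self.default_cell_params, rng)
        cell = C.CellAgent(
            self.next_cell_id(), spec.label, spec.cell_class, params, loc,
            spec.metabolism, spec.signaling, self.signaling_params,
            self.env_params["CONC_TGF"], rng,
            null_model=spec.null_model,
            can_exit_quiescence=spec.can_exit_quiescence)
        if spec.fixed_state is not None:
            cell.state = spec.fixed_state
            cell.fixed = True
        return cell

    def _initialize_populations(self):
        rng = self.rng
        for spec in self.series.populations:
            self._resolved[spec.label] = spec.resolve_params(
                self.default_cell_params)
            self._pop_by_label[spec.label] = spec
        immediate = [p for p in self.series.populations
                     if p.insert_day is None]
        delayed = [p for p in self.series.populations
                   if p.insert_day is not None]
        if self.series.init == "tissue":
            background = [p for p in immediate if p.background] or immediate
            locs = self.geom.agent_hexes()
            for loc in locs:
                spec = background[0] if len(background) == 1 else \
                    background[int(rng.integers(len(background)))]
                self.add_cell(self._make_cell(spec, loc, rng))
        else:
            # colony: seed counts at the center, interleaved across
            # populations, one agent per hexagon working outwards
            bag = []
            for spec in immediate:
                n = spec.count if spec.count is not None else 1
                bag.extend([spec] * n)
            if bag:
                order = rng.permutation(len(bag))
                locs = hex_disk(self.geom.R - 1)
                for i, k in enumerate(order):
                    u, v, w = locs[i % len(locs)]
                    self.add_cell(self._make_cell(bag[int(k)],
                                                  (u, v, w, 0), rng))
        if delayed:
            by_day: dict = {}
            for spec in delayed:
                by_day.setdefault(spec.insert_day, []).append(spec)
            for day, specs in sorted(by_day.items()):
                weights = [(s, s.fraction if s.fraction is not None else 1.0)
                           for s in specs]
                self.add_helper(C.InsertHelper(
                    int(round(day * 1440)), weights,
                    self.series.insert_radius))

    def insert_populations(self, weighted_specs, radius, rng):
        """Replace agents in the center disk with the given populations."""
        specs = [s for s, _ in weighted_specs]
        weights = np.array([w for _, w in weighted_specs], dtype=float)
        weights = weights / weights.sum()
        for (u, v, w) in hex_disk(min(radius, self.geom.R - 1)):
            loc = (u, v, w, 0)
            for cell in list(self.grid.get(loc, ())):
                self.remove_cell(cell)
            spec = specs[int(rng.choice(len(specs), p=weights))]
            self.add_cell(self._make_cell(spec, loc, rng))

    # -- stepping ----------------------------------------------------------

    def step_tick(self):
        """Advance the whole simulation by one tick (1 min)."""
        substeps = self.env_params["SUBSTEPS_PER_TICK"]
        try:
            for f in self.fields.values():
                f.step_tick(substeps)
        except FloatingPointError as exc:
            raise FloatingPointError(f"tick {self.tick}: {exc}") from exc
        scheduled = [c for c in self.cells if c.is_scheduled]
        for i in self.rng.permutation(len(scheduled)):
            C.step_cell(self, scheduled[int(i)], self.rng)
        current = self.helpers
        self.helpers = []
        for h in current:
            if h.done:
                continue
            if h.per_tick or h.due <= self.tick:
                h.step(self, self.rng)
            if not h.done:
                self.helpers.append(h)
        self.tick += 1

    def run(self, progress=False):
        """Run the full series duration, collecting snapshots in memory."""
        total = self.series.ticks
        interval = self.series.snapshot_interval
        iterator = range(total)
        if progress:  # pragma: no cover - cosmetic
            try:
                from tqdm import tqdm
                iterator = tqdm(iterator, desc=f"seed {self.seed}")
            except ImportError:
                pass
        for t in iterator:
            if t % interval == 0:
                self.snapshots.append(self.snapshot())
            self.step_tick()
        self.snapshots.append(self.snapshot())
        return self

    # -- output ------------------------------------------------------------

    def snapshot(self) -> dict:
        cells = []
        for c in self.cells:
            u, v, w, z = c.loc
            cells.append([
                c.label, c.state, u, v, w, z,
                round(c.volume, 6), round(c.age, 1),
                round(c.metab.E, 6), c.division_count,
                list(c.cycle_lengths),
                [round(c.params[k], 6) for k in C.HETEROGENEOUS_PARAMS],
            ])
        fields = {name: round(float(f.C[f.valid].mean()), 9)
                  for name, f in self.fields.items()}
        return {"tick": self.tick, "fields": fields, "cells": cells}

    def header(self) -> dict:
        s = self.series
        return {
            "series": s.name,
            "seed": self.seed,
            "radius": s.radius, "margin": s.margin, "height": s.height,
            "days": s.days, "interval": s.snapshot_interval,
            "init": s.init,
            "environment": self.env_params,
            "populations": {
                label: {"cell_class": self._pop_by_label[label].cell_class,
                        "metabolism": self._pop_by_label[label].metabolism,
                        "signaling": self._pop_by_label[label].signaling,
                        "parameters": params}
                for label, params in self._resolved.items()},
            "cell_fields": ["label", "state", "u", "v", "w", "z", "volume",
                            "age", "energy", "divisions", "cycle_lengths",
                            list(C.HETEROGENEOUS_PARAMS)],
        }

    def to_json(self) -> str:
        return json.dumps({"header": self.header(),
                           "snapshots": self.snapshots},
                          separators=(",", ":"))


def run_simulation(series: SimulationSeries, seed: int,
                   progress=False) -> Simulation:
    sim = Simulation(series, seed)
    sim.run(progress=progress)
    return sim


def run_series(series: SimulationSeries, outdir=".", progress=False):
    """Run every seed of a series; returns the written file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for seed in series.seeds:
        sim = run_simulation(series, seed, progress=progress)
        path = outdir / f"{series.name}_{seed:04d}.json"
        try:
            path.write_text(sim.to_json())
        except OSError as exc:
            raise OSError(f"failed to write output {path}: {exc}") from exc
        paths.append(path)
    return paths
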