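"""Scenario builders for growth validation and the three case studies.

The builders return :class:`~hextissue.engine.SimulationSeries` objects
ready for :func:`~hextissue.engine.run_series`:

* colony growth — a single seeded agent in an empty environment
  (in-vitro-like context);
* tissue growth — a generic background agent in every location, unable
  to exit quiescence without stimulation (in-vivo-like context), with
  representative populations introduced at t = 1 day;
* the context case study — representative populations A (crowding
  tolerance +50%), B (metabolic preference +50%), C (migratory
  threshold -50%) and baseline X, alone and in combination, in both
  contexts;
* the competition case study — a modified population (one parameter
  varied -50..+50% in 10% steps) co-seeded with a basal population at
  initial ratios 0..100% in 10% steps;
* the heterogeneity case study — representative populations with
  heterogeneity H (and background heterogeneity H₀ in tissue);
* the module-complexity grid — all 16 combinations of metabolism and
  signaling complexity, optionally with fixed-quiescent profiling
  agents.
"""

from __future__ import annotations

from .engine import PopulationSpec, SimulationSeries

#: parameter varied by each representative population and its percent delta
REPRESENTATIVE_POPULATIONS = {
    "A": ("MAX_HEIGHT", +50.0),       # crowding tolerance
    "B": ("META_PREF", +50.0),        # metabolic preference
    "C": ("MIGRA_THRESHOLD", -50.0),  # migratory threshold
    "X": (None, 0.0),                 # baseline
}

SWEEP_PARAMETERS = ("MAX_HEIGHT", "META_PREF", "MIGRA_THRESHOLD")


def representative_population(label, count=1, heterogeneity=0.0,
                              insert_day=None, fraction=None,
                              metabolism="complex", signaling="complex"):
    """Build the spec of one representative population (A, B, C or X)."""
    if label not in REPRESENTATIVE_POPULATIONS:
        raise ValueError(f"unknown representative population {label!r}")
    param, delta = REPRESENTATIVE_POPULATIONS[label]
    overrides = {param: delta} if param else {}
    return PopulationSpec(
        label=label, cell_class="C", count=count, fraction=fraction,
        percent_overrides=overrides, heterogeneity=heterogeneity,
        insert_day=insert_day, metabolism=metabolism, signaling=signaling)


def build_colony(populations=None, radius=34, margin=6, height=1,
                 days=14.0, interval=720, seeds=None, name="colony",
                 **series_kwargs) -> SimulationSeries:
    """Colony growth: agents seeded at the center of an empty grid."""
    if populations is None:
        populations = [PopulationSpec(label="X", count=1)]
    if seeds is None:
        seeds = list(range(50))
    return SimulationSeries(
        name=name, radius=radius, margin=margin, height=height, days=days,
        snapshot_interval=interval, seeds=list(seeds),
        populations=populations, init="colony", **series_kwargs)


def build_tissue(populations=None, radius=34, margin=6, height=1,
                 days=15.0, interval=720, seeds=None, name="tissue",
                 background_heterogeneity=0.0, insert_radius=5,
                 **series_kwargs) -> SimulationSeries:
    """Tissue growth: background agents everywhere; representative
    populations (if given) are introduced at t = 1 day in a center disk."""
    background = PopulationSpec(
        label="background", cell_class="C", background=True,
        can_exit_quiescence=False,
        heterogeneity=background_heterogeneity)
    pops = [background]
    for p in (populations or []):
        if p.insert_day is None:
            p.insert_day = 1.0
        pops.append(p)
    if seeds is None:
        seeds = list(range(50))
    return SimulationSeries(
        name=name, radius=radius, margin=margin, height=height, days=days,
        snapshot_interval=interval, seeds=list(seeds), populations=pops,
        init="tissue", insert_radius=insert_radius, **series_kwargs)


def parameter_sweep(param, deltas=None, context="colony", n=20, days=14.0,
                    count=1, **kwargs) -> list[SimulationSeries]:
    """Single-population sensitivity sweep of one parameter (percent)."""
    if param not in SWEEP_PARAMETERS:
        raise ValueError(f"sweep parameter must be one of {SWEEP_PARAMETERS}")
    if deltas is None:
        deltas = range(-100, 101, 10)
    out = []
    for delta in deltas:
        pop = PopulationSpec(label="mod", count=count,
                             percent_overrides={param: float(delta)})
        builder = build_colony if context == "colony" else build_tissue
        if context == "colony":
            series = builder([pop], days=days, seeds=range(n),
                             name=f"sweep_{param}_{delta:+d}", **kwargs)
        else:
            pop.insert_day = 1.0
            series = builder([pop], days=days, seeds=range(n),
                             name=f"sweep_{param}_{delta:+d}", **kwargs)
        out.append(series)
    return out


def competition_sweep(param, deltas=None, ratios=None, n=20, days=14.0,
                      total_count=10, **kwargs) -> list[SimulationSeries]:
    """Modified-vs-basal co-culture sweep (full delta x ratio factorial).

    ``ratios`` are the initial percentages of the modified population;
    counts are rounded from ``total_count`` seeded agents.
    """
    if param not in SWEEP_PARAMETERS:
        raise ValueError(f"sweep parameter must be one of {SWEEP_PARAMETERS}")
    if deltas is None:
        deltas = range(-50, 51, 10)
    if ratios is None:
        ratios = range(0, 101, 10)
    out = []
    for delta in deltas:
        for ratio in ratios:
            n_mod = int(round(total_count * ratio / 100.0))
            n_bas = total_count - n_mod
            pops = []
            if n_mod:
                pops.append(PopulationSpec(
                    label="modified", count=n_mod,
                    percent_overrides={param: float(delta)}))
            if n_bas:
                pops.append(PopulationSpec(label="basal", count=n_bas))
            out.append(build_colony(
                pops, days=days, seeds=range(n),
                name=f"comp_{param}_{delta:+d}_{ratio:03d}", **kwargs))
    return out


def heterogeneity_sweep(labels=("A", "B", "C", "X"), h_values=None,
                        context="colony", h0_values=(0.0,), n=20,
                        days=14.0, **kwargs) -> list[SimulationSeries]:
    """Heterogeneity case study: vary H (and H₀ for tissue context)."""
    if h_values is None:
        h_values = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
    out = []
    for h in h_values:
        pops = [representative_population(lbl, heterogeneity=h)
                for lbl in labels]
        if context == "colony":
            out.append(build_colony(pops, days=days, seeds=range(n),
                                    name=f"het_colony_H{h:02.0f}", **kwargs))
        else:
            for h0 in h0_values:
                pops = [representative_population(lbl, heterogeneity=h,
                                                  insert_day=1.0)
                        for lbl in labels]
                out.append(build_tissue(
                    pops, days=days, seeds=range(n),
                    background_heterogeneity=h0,
                    name=f"het_tissue_H{h:02.0f}_H0{h0:02.0f}", **kwargs))
    return out


def module_complexity_grid(n=20, days=14.0, fixed_quiescent=False,
                           modules="both", count=1,
                           **kwargs) -> list[SimulationSeries]:
    """All 16 metabolism x signaling complexity combinations.

    With ``fixed_quiescent=True`` the agents are pinned in the quiescent
    state with no rules, for profiling the environment response; then
    ``modules`` may restrict the agents to the metabolism or signaling
    module alone.
    """
    complexities = ("complex", "medium", "simple", "random")
    out = []
    for met in complexities:
        for sig in complexities:
            met_used = "none" if modules == "signaling" else met
            sig_used = "none" if modules == "metabolism" else sig
            pop = PopulationSpec(
                label="X", count=count, metabolism=met_used,
                signaling=sig_used,
                fixed_state="quiescent" if fixed_quiescent else None)
            out.append(build_colony(
                [pop], days=days, seeds=range(n),
                name=f"modules_{met}_{sig}", **kwargs))
    return out
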