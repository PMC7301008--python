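"""Simulation analysis: growth, shape, cycle and replicate statistics.

All metrics operate on a tidy snapshot table (one row per cell per
timepoint per seed) loaded from the engine's JSON output.  The three
emergent-behavior metrics quantify temporal (growth rate), spatial
(symmetry) and parametric (cycle length) emergence; the remaining
functions implement the supporting analysis formulas: doubling time,
colony and cell diameter, radial occupancy, relative fraction change,
the colony-size relationship fit, replicate parameter statistics, and
normalized sensitivity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import SYMMETRY_MAPS

HEX_SIZE_UM = 30.0           # scaling factor C, μm per hexagon
CELL_HEIGHT_UM = 4.35        # average cylindrical cell height (MAX_HEIGHT/2)


# ---------------------------------------------------------------------------
# snapshot loading
# ---------------------------------------------------------------------------

def load_snapshots(paths) -> pd.DataFrame:
    """Load engine JSON outputs into one tidy DataFrame."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for path in paths:
        doc = json.loads(Path(path).read_text())
        seed = doc["header"]["seed"]
        het_names = doc["header"]["cell_fields"][-1]
        rows = []
        for snap in doc["snapshots"]:
            tick = snap["tick"]
            for c in snap["cells"]:
                rows.append((seed, tick, c[0], c[1], c[2], c[3], c[4], c[5],
                             c[6], c[7], c[8], c[9], tuple(c[10]),
                             *c[11]))
        frames.append(pd.DataFrame(rows, columns=[
            "seed", "tick", "population", "state", "u", "v", "w", "z",
            "volume", "age", "energy", "divisions", "cycle_lengths",
            *het_names]))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["seed", "tick"], kind="stable",
                          ignore_index=True)


def cell_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Total cell count per (seed, tick)."""
    out = df.groupby(["seed", "tick"]).size().rename("count").reset_index()
    out["hours"] = out["tick"] / 60.0
    return out


# ---------------------------------------------------------------------------
# doubling time
# ---------------------------------------------------------------------------

def doubling_time(n_a, n_b, t_a_hours, t_b_hours) -> float:
    """Count-based doubling time (t_b - t_a) ln2 / ln(N_b/N_a), hours."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("cell counts must be positive")
    if n_b <= n_a:
        return float("nan")
    return (t_b_hours - t_a_hours) * np.log(2.0) / np.log(n_b / n_a)


def fit_exponential(t_hours, counts):
    """Least-squares fit of N = N0 exp(r t); returns (N0, r, r²).

    The coefficient of determination is computed on the raw counts.
    """
    t = np.asarray(t_hours, dtype=float)
    n = np.asarray(counts, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least three timepoints")
    # log-linear start values, refined by non-linear least squares
    b, a = np.polyfit(t, np.log(np.maximum(n, 1e-9)), 1)
    try:
        popt, _ = optimize.curve_fit(lambda tt, n0, r: n0 * np.exp(r * tt),
                                     t, n, p0=[np.exp(a), b], maxfev=10000)
    except RuntimeError:
        popt = [np.exp(a), b]
    n0, r = float(popt[0]), float(popt[1])
    resid = n - n0 * np.exp(r * t)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((n - n.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return n0, r, r2


def doubling_time_expfit(t_hours, counts) -> float:
    """Doubling time ln2 / r from an exponential fit, hours."""
    _, r, _ = fit_exponential(t_hours, counts)
    if r <= 0:
        return float("nan")
    return float(np.log(2.0) / r)


# ---------------------------------------------------------------------------
# geometry-derived metrics
# ---------------------------------------------------------------------------

def colony_diameter(locations, hex_size=HEX_SIZE_UM) -> float:
    """Mean diameter across the three hexagonal axes, μm.

    D = C [max(u_max-u_min+1, 0) + ... ] / 3 over all occupied locations.
    """
    locs = list(locations)
    if not locs:
        return 0.0
    arr = np.asarray([(l[0], l[1], l[2]) for l in locs], dtype=float)
    span = arr.max(axis=0) - arr.min(axis=0) + 1.0
    return float(hex_size * np.maximum(span, 0.0).sum() / 3.0)


def cell_diameter(volume, height=CELL_HEIGHT_UM) -> float:
    """Diameter of a cylindrical cell of the given volume, μm."""
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0):
        raise ValueError("cell volume must be positive")
    return 2.0 * np.sqrt(v / (np.pi * height))


def fraction_occupancy(n_agents: int, r: int) -> float:
    """Agents per maximum locations at radius r (may exceed 1)."""
    n_r = 1 if r == 0 else 6 * r
    return n_agents / n_r


def relative_fraction_change(x: float, x0: float) -> float:
    """(x - x0)/s with s = 1 - x0 for increases, x0 for decreases."""
    dx = x - x0
    s = (1.0 - x0) if dx > 0 else x0
    if s == 0.0:
        return 0.0
    return dx / s


# ---------------------------------------------------------------------------
# emergent-behavior metrics
# ---------------------------------------------------------------------------

def growth_rate(times_days, diameters, start_day=1.0) -> pd.DataFrame:
    """Expanding-window least-squares slopes of colony diameter, μm/day.

    For each window end t_i the slope of a degree-1 polynomial fit over
    the timepoints in [start_day, t_i] is reported.  Windows with fewer
    than two points yield NaN.
    """
    t = np.asarray(times_days, dtype=float)
    d = np.asarray(diameters, dtype=float)
    order = np.argsort(t)
    t, d = t[order], d[order]
    base = t >= start_day - 1e-9
    ends, slopes = [], []
    for t_i in t[base][1:]:
        sel = base & (t <= t_i + 1e-9)
        ends.append(t_i)
        if sel.sum() < 2:
            slopes.append(float("nan"))
        else:
            slopes.append(float(np.polyfit(t[sel], d[sel], 1)[0]))
    return pd.DataFrame({"window_end_day": ends, "growth_rate": slopes})


def symmetry(locations) -> float:
    """Six-fold rotational symmetry of the occupied locations, in [0, 1].

    For every unique occupied (u, v, w) the five rotational counterparts
    are checked; the score is 1 - mean unoccupied fraction.  For 3D
    snapshots the score is computed per layer and averaged.
    """
    locs = list(locations)
    if not locs:
        raise ValueError("symmetry undefined for an empty snapshot")
    by_layer: dict = {}
    for l in locs:
        z = l[3] if len(l) > 3 else 0
        by_layer.setdefault(z, set()).add((l[0], l[1], l[2]))
    scores = []
    for occ in by_layer.values():
        total = 0.0
        for (u, v, w) in occ:
            missing = sum(1 for f in SYMMETRY_MAPS if f(u, v, w) not in occ)
            total += missing / 5.0
        scores.append(1.0 - total / len(occ))
    return float(np.mean(scores))


def cycle_length(cycle_lists) -> float:
    """Two-stage mean cell-cycle length in hours.

    ``cycle_lists`` holds, per agent, the completed cycle lengths in
    minutes; lengths are averaged within each agent first, then across
    agents with at least one completed cycle.
    """
    per_agent = [np.mean(c) for c in cycle_lists if len(c) > 0]
    if not per_agent:
        return float("nan")
    return float(np.mean(per_agent) / 60.0)


# ---------------------------------------------------------------------------
# data fitting
# ---------------------------------------------------------------------------

def fit_colony_size(n, D, d):
    """Fit n = a D^b / d^c by non-linear least squares; returns (a, b, c).

    Raises RuntimeError with diagnostics if the optimizer fails.
    """
    n = np.asarray(n, float)
    D = np.asarray(D, float)
    d = np.asarray(d, float)
    if len(n) < 3:
        raise ValueError("need at least three (n, D, d) triples")
    if np.any(n <= 0) or np.any(D <= 0) or np.any(d <= 0):
        raise ValueError("colony-size fit requires positive data")

    def model(X, a, b, c):
        DD, dd = X
        return a * DD ** b / dd ** c

    # log-linear start values
    A = np.column_stack([np.ones_like(n), np.log(D), -np.log(d)])
    coef, *_ = np.linalg.lstsq(A, np.log(n), rcond=None)
    p0 = [float(np.exp(coef[0])), float(coef[1]), float(coef[2])]
    try:
        popt, _ = optimize.curve_fit(model, (D, d), n, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"colony-size fit did not converge (start {p0}): {exc}") from exc
    return tuple(float(p) for p in popt)


def parameter_statistics(baseline, current):
    """Replicate-average parameter statistics versus the initial state.

    ``baseline`` and ``current`` are paired per-replicate averages of a
    cell parameter (same seed order).  Returns mean, sample s.d., the
    paired t-test for a location shift and Levene's test for a variance
    change.
    """
    b = np.asarray(baseline, float)
    c = np.asarray(current, float)
    if len(b) != len(c) or len(b) < 2:
        raise ValueError("need paired samples from at least two replicates")
    t_stat, t_p = stats.ttest_rel(c, b)
    l_stat, l_p = stats.levene(c, b)
    return {
        "mean": float(c.mean()),
        "sd": float(c.std(ddof=1)),
        "baseline_mean": float(b.mean()),
        "baseline_sd": float(b.std(ddof=1)),
        "shift_t": float(t_stat), "shift_p": float(t_p),
        "levene_W": float(l_stat), "levene_p": float(l_p),
    }


def sensitivity(y, y0, x, x0) -> float:
    """Normalized sensitivity (y - y0) x0 / ((x - x0) y0)."""
    if x == x0:
        raise ValueError("sensitivity undefined at x = x0")
    if y0 == 0:
        raise ValueError("sensitivity undefined for y0 = 0")
    return (y - y0) * x0 / ((x - x0) * y0)


# ---------------------------------------------------------------------------
# table-level conveniences
# ---------------------------------------------------------------------------

def colony_diameters(df: pd.DataFrame, hex_size=HEX_SIZE_UM) -> pd.DataFrame:
    """Colony diameter per (seed, tick), μm."""
    rows = []
    for (seed, tick), grp in df.groupby(["seed", "tick"]):
        locs = set(zip(grp["u"], grp["v"], grp["w"]))
        rows.append((seed, tick, colony_diameter(locs, hex_size)))
    out = pd.DataFrame(rows, columns=["seed", "tick", "diameter"])
    out["days"] = out["tick"] / 1440.0
    return out


def state_by_radius(df_at_tick: pd.DataFrame) -> pd.DataFrame:
    """Fraction occupancy of each state as a function of radius."""
    g = df_at_tick.copy()
    g["r"] = ((g["u"].abs() + g["v"].abs() + g["w"].abs()) // 2).astype(int)
    rows = []
    for (r, state), grp in g.groupby(["r", "state"]):
        rows.append((r, state, fraction_occupancy(len(grp), r)))
    return pd.DataFrame(rows, columns=["r", "state", "occupancy"])


ACTIVE_STATES = ("proliferative", "migratory")


def active_rim_width(df_at_tick: pd.DataFrame, min_occupancy: float = 0.25
                     ) -> int:
    """Width (in hexes) of the active rim of a colony snapshot.

    The rim is the contiguous outer band of radii in which active
    (proliferative + migratory) cells form the majority, surrounding
    the inactive (quiescent/senescent/necrotic/apoptotic) core.  Radii
    whose fraction occupancy falls below ``min_occupancy`` — isolated
    migratory wanderers outside the colony body — are not part of the
    colony and are skipped.
    """
    g = df_at_tick.copy()
    g["r"] = ((g["u"].abs() + g["v"].abs() + g["w"].abs()) // 2).astype(int)
    width = 0
    started = False
    for r in sorted(g["r"].unique(), reverse=True):
        at_r = g[g["r"] == r]
        occ = fraction_occupancy(len(at_r), r)
        if not started and occ < min_occupancy:
            continue
        started = True
        active = at_r["state"].isin(ACTIVE_STATES).sum()
        if 2 * active > len(at_r):
            width += 1
        else:
            break
    return width


def tidy_metric_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-seed, per-timepoint values of the standard metric suite."""
    counts = cell_counts(df)
    diam = colony_diameters(df)
    rows = []
    for seed, grp in df.groupby("seed"):
        for tick, snap in grp.groupby("tick"):
            locs = set(zip(snap["u"], snap["v"], snap["w"], snap["z"]))
            rows.append((seed, tick, "symmetry", symmetry(locs)))
            rows.append((seed, tick, "cycle_length",
                         cycle_length(snap["cycle_lengths"])))
    tidy = pd.DataFrame(rows, columns=["seed", "tick", "metric", "value"])
    counts_t = counts.melt(["seed", "tick"], ["count"], "metric", "value")
    diam_t = diam.melt(["seed", "tick"], ["diameter"], "metric", "value")
    return pd.concat([tidy, counts_t, diam_t], ignore_index=True)
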